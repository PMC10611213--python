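"""Reference compound–target library: data model, I/O and potency normalization.

The library is the "chemical structural neighbor" universe every prediction
method searches: a compound table (SMILES + canonical form), a target table
(closed class vocabulary), an activity table normalized to pActivity =
−log10(concentration in mol/L), and a per-compound descriptor cache keyed by
canonical SMILES.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem

TARGET_CLASSES = (
    "GPCR", "Enzyme", "Kinase", "NuclearReceptor", "IonChannel",
    "Cytochrome", "Transporter", "OtherFamilies", "Unclassified",
)

ACTIVITY_TYPES = ("IC50", "Ki", "EC50", "Kd")

ACTIVITY_COLUMNS = ["compound_id", "smiles", "target_id", "target_class",
                    "activity_type", "value_nm", "moa", "source"]

#: Default potency cutoff (pActivity ≥ 5.0, i.e. 10 µM) defining a target's
#: ligand set; configurable everywhere it is used.
DEFAULT_LIGAND_CUTOFF = 5.0


class LibraryError(ValueError):
    pass


def to_pactivity(value_nm: float) -> float:
    """pActivity = −log10(value in mol/L) = 9 − log10(value in nM)."""
    if value_nm <= 0:
        raise LibraryError(f"activity value must be positive, got {value_nm}")
    return 9.0 - math.log10(value_nm)


def pactivity_to_nm(pactivity: float) -> float:
    return 10.0 ** (9.0 - pactivity)


@dataclass
class LoadReport:
    n_compounds: int = 0
    n_targets: int = 0
    n_activities: int = 0
    n_duplicates_collapsed: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class ReferenceLibrary:
    """Compound, target and activity tables plus a descriptor cache."""

    compounds: pd.DataFrame          # compound_id, smiles, canonical_smiles, name
    targets: pd.DataFrame            # target_id, gene_symbol, target_class, species
    activities: pd.DataFrame         # compound_id, target_id, activity_type,
                                     #   value_nm, pactivity, moa, source
    descriptors: dict = field(default_factory=dict, repr=False)
    molecules: dict = field(default_factory=dict, repr=False)   # compound_id -> Molecule

    # -- accessors ---------------------------------------------------------
    def compound_ids(self) -> list[str]:
        return self.compounds["compound_id"].tolist()

    def target_ids(self) -> list[str]:
        return self.targets["target_id"].tolist()

    def molecule(self, compound_id: str) -> chem.Molecule:
        if compound_id not in self.molecules:
            row = self.compounds.loc[self.compounds["compound_id"] == compound_id]
            if row.empty:
                raise LibraryError(f"unknown compound {compound_id!r}")
            self.molecules[compound_id] = chem.parse_smiles(
                row["smiles"].iloc[0], mol_id=compound_id)
        return self.molecules[compound_id]

    def ligand_set(self, target_id: str,
                   cutoff: float = DEFAULT_LIGAND_CUTOFF) -> list[str]:
        """Compound ids with pActivity ≥ cutoff against the target, sorted."""
        if target_id not in set(self.targets["target_id"]):
            raise LibraryError(f"unknown target {target_id!r}")
        sub = self.activities[(self.activities["target_id"] == target_id)
                              & (self.activities["pactivity"] >= cutoff)]
        return sorted(set(sub["compound_id"]))

    # -- descriptor cache --------------------------------------------------
    def build_descriptor_cache(self, max_path_len: int = 7, bits: int = 2048,
                               dmax: int = 10, phrag_len: int = 7) -> None:
        """Precompute fingerprint / features / FPD / SHED / PHRAG per compound."""
        for cid in self.compound_ids():
            mol = self.molecule(cid)
            key = mol.smiles
            if key in self.descriptors:
                continue
            feats = chem.assign_features(mol)
            fpd = chem.compute_fpd(mol, feats, dmax=dmax)
            self.descriptors[key] = {
                "fingerprint": chem.compute_fingerprint(mol, max_path_len, bits),
                "features": feats,
                "fpd": fpd,
                "shed": chem.compute_shed(fpd),
                "phrag": chem.compute_phrag(mol, feats, max_len=phrag_len),
            }

    def descriptor(self, compound_id: str, kind: str):
        mol = self.molecule(compound_id)
        if mol.smiles not in self.descriptors:
            raise LibraryError(
                "descriptor cache not built; call build_descriptor_cache() first")
        return self.descriptors[mol.smiles][kind]

    # -- integrity ---------------------------------------------------------
    def check_integrity(self) -> list[str]:
        """Referential-integrity violations (empty list when consistent)."""
        problems = []
        cids = set(self.compounds["compound_id"])
        tids = set(self.targets["target_id"])
        if len(cids) != len(self.compounds):
            problems.append("duplicate compound ids")
        if len(tids) != len(self.targets):
            problems.append("duplicate target ids")
        bad_c = set(self.activities["compound_id"]) - cids
        bad_t = set(self.activities["target_id"]) - tids
        if bad_c:
            problems.append(f"activities reference unknown compounds: {sorted(bad_c)[:5]}")
        if bad_t:
            problems.append(f"activities reference unknown targets: {sorted(bad_t)[:5]}")
        bad_class = set(self.targets["target_class"]) - set(TARGET_CLASSES)
        if bad_class:
            problems.append(f"unknown target classes: {sorted(bad_class)}")
        if (self.activities["value_nm"] <= 0).any():
            problems.append("non-positive activity values")
        return problems

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        """Persist as a directory of TSVs plus a JSON manifest (byte-stable)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        comp = self.compounds.sort_values("compound_id").reset_index(drop=True)
        targ = self.targets.sort_values("target_id").reset_index(drop=True)
        act = self.activities.sort_values(
            ["compound_id", "target_id", "activity_type"]).reset_index(drop=True)
        comp.to_csv(directory / "compounds.tsv", sep="\t", index=False)
        targ.to_csv(directory / "targets.tsv", sep="\t", index=False)
        act.to_csv(directory / "activities.tsv", sep="\t", index=False,
                   float_format="%.6f")
        manifest = {
            "format": "offtarget-library-v1",
            "n_compounds": int(len(comp)),
            "n_targets": int(len(targ)),
            "n_activities": int(len(act)),
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory) -> "ReferenceLibrary":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("format") != "offtarget-library-v1":
            raise LibraryError("unrecognized library manifest")
        return cls(
            compounds=pd.read_csv(directory / "compounds.tsv", sep="\t"),
            targets=pd.read_csv(directory / "targets.tsv", sep="\t"),
            activities=pd.read_csv(directory / "activities.tsv", sep="\t"),
        )


def _collapse_duplicates(activities: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse replicate (compound, target, type) rows to the most potent value."""
    n_before = len(activities)
    idx = activities.groupby(
        ["compound_id", "target_id", "activity_type"], sort=True)["value_nm"].idxmin()
    collapsed = activities.loc[sorted(idx)].reset_index(drop=True)
    return collapsed, n_before - len(collapsed)


def load_library(activities_csv, compounds_path=None,
                 sep: str | None = None) -> tuple[ReferenceLibrary, LoadReport]:
    """Build a :class:`ReferenceLibrary` from an activity table.

    The activity table (CSV or TSV, sniffed by extension unless ``sep`` is
    given) must carry the documented columns::

        compound_id, smiles, target_id, target_class, activity_type,
        value_nm, moa, source

    ``compounds_path`` optionally supplies structures (SMILES list or SDF)
    overriding the activity table's ``smiles`` column by compound id. Rows
    with unparsable SMILES or non-positive values are rejected and counted,
    never silently dropped.
    """
    report = LoadReport()
    path = Path(activities_csv)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str, "target_id": str})
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"activity table missing required columns: {missing}")

    smiles_override: dict[str, str] = {}
    if compounds_path is not None:
        cpath = Path(compounds_path)
        mols, rej = (chem.read_sdf(cpath) if cpath.suffix.lower() == ".sdf"
                     else chem.read_smiles_file(cpath))
        report.rejected.extend(rej)
        smiles_override = {m.id: m.smiles for m in mols}

    rows = []
    canonical: dict[str, str] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        cid = str(row.compound_id)
        smi = smiles_override.get(cid, str(row.smiles))
        try:
            value = float(row.value_nm)
            pact = to_pactivity(value)
        except (LibraryError, ValueError) as exc:
            report.rejected.append((pos, f"bad activity value: {exc}"))
            continue
        if str(row.activity_type) not in ACTIVITY_TYPES:
            report.rejected.append((pos, f"unknown activity type {row.activity_type!r}"))
            continue
        if cid not in canonical:
            try:
                canonical[cid] = chem.parse_smiles(smi).smiles
            except chem.ChemError as exc:
                report.rejected.append((pos, str(exc)))
                canonical[cid] = ""
                continue
        elif canonical[cid] == "":
            report.rejected.append((pos, f"compound {cid} previously failed to parse"))
            continue
        rows.append({
            "compound_id": cid, "smiles": smi, "canonical_smiles": canonical[cid],
            "target_id": str(row.target_id), "target_class": str(row.target_class),
            "activity_type": str(row.activity_type), "value_nm": value,
            "pactivity": pact,
            "moa": str(row.moa) if pd.notna(row.moa) else "unknown",
            "source": str(row.source) if pd.notna(row.source) else "",
        })

    if not rows:
        raise LibraryError("no valid activity rows")
    full = pd.DataFrame(rows)
    activities, n_dup = _collapse_duplicates(
        full[["compound_id", "target_id", "activity_type", "value_nm",
              "pactivity", "moa", "source"]])
    report.n_duplicates_collapsed = n_dup

    compounds = (full[["compound_id", "smiles", "canonical_smiles"]]
                 .drop_duplicates("compound_id").sort_values("compound_id")
                 .reset_index(drop=True))
    compounds["name"] = compounds["compound_id"]
    targets = (full[["target_id", "target_class"]]
               .drop_duplicates("target_id").sort_values("target_id")
               .reset_index(drop=True))
    targets["gene_symbol"] = targets["target_id"]
    targets["species"] = "human"
    targets = targets[["target_id", "gene_symbol", "target_class", "species"]]

    lib = ReferenceLibrary(compounds=compounds, targets=targets, activities=activities)
    report.n_compounds = len(compounds)
    report.n_targets = len(targets)
    report.n_activities = len(activities)
    problems = lib.check_integrity()
    if problems:
        raise LibraryError(f"library integrity violations: {problems}")
    return lib, report


def from_frames(compounds: pd.DataFrame, targets: pd.DataFrame,
                activities: pd.DataFrame) -> ReferenceLibrary:
    """Assemble a library from pre-validated frames (used by the generator)."""
    if "pactivity" not in activities.columns:
        activities = activities.assign(
            pactivity=[to_pactivity(v) for v in activities["value_nm"]])
    lib = ReferenceLibrary(compounds=compounds.reset_index(drop=True),
                           targets=targets.reset_index(drop=True),
                           activities=activities.reset_index(drop=True))
    problems = lib.check_integrity()
    if problems:
        raise LibraryError(f"library integrity violations: {problems}")
    return lib
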