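"""Molecular graphs, pharmacophore typing, 2D descriptors and physchem profiling.

Everything downstream of this module works on the 2D molecular graph: hashed
linear-path bit fingerprints for Tanimoto comparison, pharmacophore
feature-pair distance distributions (FPD), their Shannon-entropy summaries
(SHED), pharmacophoric fragment strings (PHRAG), and a physicochemical
profile (MW, logP, TPSA, H-bond counts, rotatable bonds) used for the
logP/TPSA "3/75" risk classification.

RDKit supplies parsing, canonicalization, SMARTS matching and the published
Crippen/Ertl contribution models; the descriptor constructions themselves are
defined here and versioned.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# errors

class ChemError(ValueError):
    """Base class for chemistry-layer failures."""


class ParseError(ChemError):
    """Malformed SMILES / SDF input."""


class ValenceError(ChemError):
    """Chemically impossible structure (valence violation)."""


# ---------------------------------------------------------------------------
# molecule

UNREACHABLE = -1  # sentinel for topological distance between fragments


@dataclass(frozen=True)
class Molecule:
    """A 2D molecular graph with a canonical SMILES serialization."""

    rdmol: Chem.Mol = field(compare=False, repr=False)
    smiles: str                 # canonical form
    source: str                 # the text it was parsed from
    id: str = ""

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    def atom_symbols(self) -> list[str]:
        return [a.GetSymbol() for a in self.rdmol.GetAtoms()]


def parse_smiles(text: str, mol_id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises :class:`ParseError` on malformed input and :class:`ValenceError`
    when the graph parses but cannot be sanitized (impossible valence).
    """
    if not text or not text.strip():
        raise ParseError("empty SMILES string")
    text = text.strip()
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise ParseError(f"malformed SMILES {text!r} (unparsable near position 0..{len(text)})")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types here
        raise ValenceError(f"chemistry error in {text!r}: {exc}") from exc
    return Molecule(rdmol=mol, smiles=Chem.MolToSmiles(mol), source=text, id=mol_id)


def read_smiles_file(path) -> tuple[list[Molecule], list[tuple[int, str]]]:
    """Read a plain-text SMILES file (``smiles[<TAB>id]`` per line).

    Returns (molecules, rejections) where each rejection is (1-based line
    number, reason). Blank lines and ``#`` comments are skipped.
    """
    mols: list[Molecule] = []
    rejected: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0]
            mid = parts[1] if len(parts) > 1 else f"line{lineno}"
            try:
                mols.append(parse_smiles(smi, mol_id=mid))
            except ChemError as exc:
                rejected.append((lineno, str(exc)))
    return mols, rejected


def read_sdf(path) -> tuple[list[Molecule], list[tuple[int, str]]]:
    """Read an SDF (V2000) file; returns (molecules, rejections by record index)."""
    mols: list[Molecule] = []
    rejected: list[tuple[int, str]] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            rejected.append((idx, "unreadable SDF record"))
            continue
        mid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{idx}"
        mols.append(Molecule(rdmol=mol, smiles=Chem.MolToSmiles(mol),
                             source=Chem.MolToSmiles(mol), id=mid))
    return mols, rejected


# ---------------------------------------------------------------------------
# pharmacophore feature typing

FEATURE_VOCABULARY = ("ACC", "ARO", "DON", "HYD", "NEG", "POS")

#: Unordered feature pairs (21 of them), the row index of FPD / SHED.
FEATURE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(FEATURE_VOCABULARY, 2)
)

# Versioned rule table. DON: N/O/S bearing H; ACC: N/O with an available lone
# pair (amide N and nitro O excluded); ARO: aromatic-perceived atoms; HYD:
# non-aromatic C, divalent S or halogen away from polar atoms; POS/NEG:
# groups charged at physiological pH (formal charges plus aliphatic amines /
# carboxylic acids).
_RULE_TABLES: dict[str, dict[str, str]] = {
    "v1": {
        "DON": "[$([N;!H0;v3,v4&+1]),$([O;H1;+0]),$([S;H1;+0])]",
        "ACC": ("[$([O;H1;v2]),$([O;H0;v2;!$(O=N)]),"
                "$([O;X1;$([OX1]=[C,S,P]);!$([OX1]=[N])]),"
                "$([N;v3;X3;H0;!$(N=O);!$([n])]),$([N;v3;X2]),$([n;X2])]"),
        "ARO": "[a]",
        "HYD": "[$([C;!a;!$(C~[N,O,F])]),$([S;X2;!$(S~[N,O])]),F,Cl,Br,I]",
        "POS": "[$([+1,+2;!$([N+][O-])]),$([N;X3;H2,H1;v3;$(N[C;X4])])]",
        "NEG": "[$([-1,-2]),$([O;H1]C=O)]",
    }
}

_COMPILED: dict[str, dict[str, Chem.Mol]] = {}


def _compiled_rules(rule_table: str) -> dict[str, Chem.Mol]:
    if rule_table not in _RULE_TABLES:
        raise ChemError(f"unknown pharmacophore rule table {rule_table!r}; "
                        f"registered: {sorted(_RULE_TABLES)}")
    if rule_table not in _COMPILED:
        _COMPILED[rule_table] = {
            label: Chem.MolFromSmarts(smarts)
            for label, smarts in _RULE_TABLES[rule_table].items()
        }
    return _COMPILED[rule_table]


@dataclass(frozen=True)
class FeatureAssignment:
    """Per-atom pharmacophore label sets for one molecule."""

    labels: tuple[frozenset[str], ...]
    rule_table: str

    def featured_atoms(self) -> list[int]:
        return [i for i, labs in enumerate(self.labels) if labs]


def assign_features(mol: Molecule, rule_table: str = "v1") -> FeatureAssignment:
    """Assign pharmacophore labels to every atom; pure function of the graph."""
    patterns = _compiled_rules(rule_table)
    labels: list[set[str]] = [set() for _ in range(mol.n_atoms)]
    for label, pattern in patterns.items():
        for match in mol.rdmol.GetSubstructMatches(pattern, maxMatches=10000):
            labels[match[0]].add(label)
    # invariant: aromatic-perceived atoms always carry ARO
    for atom in mol.rdmol.GetAtoms():
        if atom.GetIsAromatic():
            labels[atom.GetIdx()].add("ARO")
    return FeatureAssignment(labels=tuple(frozenset(s) for s in labels),
                             rule_table=rule_table)


# ---------------------------------------------------------------------------
# topological distances

def topological_distances(mol: Molecule) -> np.ndarray:
    """Bond-count distance matrix; ``UNREACHABLE`` (−1) between fragments."""
    if mol.n_atoms == 0:
        return np.zeros((0, 0), dtype=int)
    dm = Chem.GetDistanceMatrix(mol.rdmol)
    out = dm.astype(float)
    out[out > 1e7] = UNREACHABLE  # rdkit marks disconnected pairs with 1e8
    return out.astype(int)


# ---------------------------------------------------------------------------
# hashed linear-path fingerprint

@dataclass(frozen=True)
class BitFingerprint:
    """Sparse bit set from hashed linear atom paths (generator is versioned)."""

    bits: frozenset[int]
    size: int
    generator: str = "linpath-v1"

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.size:
            raise ChemError("bit index exceeds fingerprint size")


def _atom_label(atom: Chem.Atom) -> str:
    lab = atom.GetSymbol()
    if atom.GetIsAromatic():
        lab += "a"
    if atom.GetFormalCharge():
        lab += f"{atom.GetFormalCharge():+d}"
    return lab


_BOND_LABEL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _path_strings(mol: Molecule, max_path_len: int) -> set[str]:
    """All linear-path label strings of 1..max_path_len atoms, canonical direction."""
    rd = mol.rdmol
    atom_labels = [_atom_label(a) for a in rd.GetAtoms()]
    bond_labels: dict[tuple[int, int], str] = {}
    adj: list[list[int]] = [[] for _ in range(rd.GetNumAtoms())]
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        lab = _BOND_LABEL.get(b.GetBondType(), "~")
        bond_labels[(i, j)] = bond_labels[(j, i)] = lab
        adj[i].append(j)
        adj[j].append(i)
    strings: set[str] = set(atom_labels)  # single-atom paths

    def grow(path: list[int], text: str) -> None:
        if len(path) > 1:
            # emit in canonical (lexicographically smaller) direction
            rev_parts: list[str] = []
            for k in range(len(path) - 1, 0, -1):
                rev_parts.append(atom_labels[path[k]])
                rev_parts.append(bond_labels[(path[k], path[k - 1])])
            rev_parts.append(atom_labels[path[0]])
            strings.add(min(text, "".join(rev_parts)))
        if len(path) == max_path_len:
            return
        tail = path[-1]
        for nxt in adj[tail]:
            if nxt not in path:
                grow(path + [nxt], text + bond_labels[(tail, nxt)] + atom_labels[nxt])

    for start in range(rd.GetNumAtoms()):
        grow([start], atom_labels[start])
    return strings


def compute_fingerprint(mol: Molecule, max_path_len: int = 7,
                        bits: int = 2048) -> BitFingerprint:
    """Hashed linear-path fingerprint (paths of 1..max_path_len atoms).

    Deterministic (stable blake2b hashing) and invariant to atom reindexing.
    """
    if max_path_len < 1:
        raise ChemError("max_path_len must be >= 1")
    if bits < 1 or bits & (bits - 1):
        raise ChemError("bit-space size must be a power of two")
    on = frozenset(
        int.from_bytes(hashlib.blake2b(s.encode(), digest_size=8).digest(), "big") % bits
        for s in _path_strings(mol, max_path_len)
    )
    return BitFingerprint(bits=on, size=bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B|; 0 for two empty sets (warned)."""
    if a.size != b.size:
        raise ChemError(f"fingerprint bit-space mismatch: {a.size} vs {b.size}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    return len(a.bits & b.bits) / union


# ---------------------------------------------------------------------------
# FPD / SHED / PHRAG

@dataclass(frozen=True)
class FPDMatrix:
    """Feature-pair distance histogram: 21 pairs × (Dmax bins + overflow)."""

    counts: np.ndarray          # shape (21, dmax + 1), bin k = distance k+1, last = overflow
    dmax: int
    normalized: bool = False

    def pair_row(self, a: str, b: str) -> np.ndarray:
        key = tuple(sorted((a, b)))
        return self.counts[FEATURE_PAIRS.index(key)]  # type: ignore[arg-type]

    def normalize(self) -> "FPDMatrix":
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(sums > 0, self.counts / sums, 0.0)
        return FPDMatrix(counts=probs, dmax=self.dmax, normalized=True)

    def flatten(self) -> np.ndarray:
        return self.counts.ravel().astype(float)


def compute_fpd(mol: Molecule, features: FeatureAssignment, dmax: int = 10) -> FPDMatrix:
    """Count, for each unordered feature pair, the topological distances between
    featured atom pairs; distances > dmax go to the overflow bin."""
    if dmax < 2:
        raise ChemError("dmax must be >= 2")
    counts = np.zeros((len(FEATURE_PAIRS), dmax + 1), dtype=float)
    featured = features.featured_atoms()
    if len(featured) < 2:
        return FPDMatrix(counts=counts, dmax=dmax)
    pair_index = {pair: k for k, pair in enumerate(FEATURE_PAIRS)}
    dm = topological_distances(mol)
    for i, j in itertools.combinations(featured, 2):
        d = int(dm[i, j])
        if d <= 0:  # same atom or disconnected
            continue
        col = min(d, dmax + 1) - 1
        for la in features.labels[i]:
            for lb in features.labels[j]:
                counts[pair_index[tuple(sorted((la, lb)))], col] += 1
    return FPDMatrix(counts=counts, dmax=dmax)


@dataclass(frozen=True)
class SHEDVector:
    """Natural-log Shannon entropy of each feature pair's distance histogram."""

    entropies: np.ndarray       # shape (21,), aligned with FEATURE_PAIRS
    dmax: int

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(zip(FEATURE_PAIRS, self.entropies))


def shannon_entropy(histogram: np.ndarray) -> float:
    """H = −Σ p ln p over the normalized histogram; 0 for an empty histogram."""
    total = histogram.sum()
    if total <= 0:
        return 0.0
    p = histogram[histogram > 0] / total
    return float(-(p * np.log(p)).sum())


def compute_shed(fpd: FPDMatrix) -> SHEDVector:
    ent = np.array([shannon_entropy(row) for row in fpd.counts])
    return SHEDVector(entropies=ent, dmax=fpd.dmax)


@dataclass(frozen=True)
class PHRAGProfile:
    """Multiset of feature-label strings along shortest paths between featured atoms."""

    fragments: tuple[tuple[str, int], ...]   # sorted (string, count) pairs

    def as_counter(self) -> Counter:
        return Counter(dict(self.fragments))


def _path_label(features: FeatureAssignment, atom_idx: int) -> str:
    labs = features.labels[atom_idx]
    return "+".join(sorted(labs)) if labs else "."


def _all_shortest_paths(adj: list[list[int]], src: int, dst: int,
                        cap: int = 64) -> list[list[int]]:
    """Every shortest path src→dst (BFS predecessor DAG), capped for safety."""
    from collections import deque

    dist = {src: 0}
    preds: dict[int, list[int]] = {src: []}
    queue = deque([src])
    while queue:
        v = queue.popleft()
        if v == dst:
            break
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                preds[w] = [v]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                preds[w].append(v)
    if dst not in dist:
        return []
    if src == dst:
        return [[src]]
    paths: list[list[int]] = []

    def dfs(node: int, acc: list[int]) -> None:
        if len(paths) >= cap:
            return
        acc = [node] + acc
        if node == src:
            paths.append(acc)
            return
        for p in preds[node]:
            dfs(p, acc)

    dfs(dst, [])
    return paths


def compute_phrag(mol: Molecule, features: FeatureAssignment, max_len: int = 7) -> PHRAGProfile:
    """Feature-label string per featured atom pair, taken along its shortest
    path spanning 2..max_len atoms. Among equally short paths the
    lexicographically smallest label string (either direction) is used, so
    the profile is invariant to atom reindexing."""
    if max_len < 2:
        raise ChemError("max_len must be >= 2")
    featured = features.featured_atoms()
    counter: Counter = Counter()
    if len(featured) >= 2:
        rd = mol.rdmol
        adj = [[nb.GetIdx() for nb in a.GetNeighbors()] for a in rd.GetAtoms()]
        for i, j in itertools.combinations(featured, 2):
            paths = _all_shortest_paths(adj, i, j)
            if not paths or not (2 <= len(paths[0]) <= max_len):
                continue
            best = None
            for path in paths:
                fwd = "-".join(_path_label(features, k) for k in path)
                rev = "-".join(_path_label(features, k) for k in reversed(path))
                cand = min(fwd, rev)
                if best is None or cand < best:
                    best = cand
            counter[best] += 1
    return PHRAGProfile(fragments=tuple(sorted(counter.items())))


# ---------------------------------------------------------------------------
# physicochemical profile

_AMIDE = Chem.MolFromSmarts("C(=O)[NX3]")


@dataclass(frozen=True)
class PhyschemProfile:
    mw: float                   # g/mol, implicit H included
    logp: float                 # Crippen atomic contributions
    logs: float                 # ESOL-style aqueous solubility estimate
    tpsa: float                 # Ertl fragment sums, Å²
    hbd: int
    hba: int
    amide_count: int
    rotatable_bonds: int


def compute_physchem(mol: Molecule) -> PhyschemProfile:
    rd = mol.rdmol
    mw = Descriptors.MolWt(rd)
    logp = Crippen.MolLogP(rd)
    # ESOL (Delaney) estimate: intercept + logP, MW, rotatable-bond and
    # aromatic-proportion terms.
    heavy = rd.GetNumHeavyAtoms()
    arom_prop = (sum(a.GetIsAromatic() for a in rd.GetAtoms()) / heavy) if heavy else 0.0
    rot = rdMolDescriptors.CalcNumRotatableBonds(rd)
    logs = 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rot - 0.74 * arom_prop
    return PhyschemProfile(
        mw=mw,
        logp=logp,
        logs=logs,
        tpsa=rdMolDescriptors.CalcTPSA(rd),
        hbd=rdMolDescriptors.CalcNumHBD(rd),
        hba=rdMolDescriptors.CalcNumHBA(rd),
        amide_count=len(rd.GetSubstructMatches(_AMIDE)),
        rotatable_bonds=rot,
    )


def classify_rule_3_75(profile: PhyschemProfile) -> str:
    """logP/TPSA risk partition: ``compliant`` (logP < 3 and TPSA > 75),
    ``lipophilic`` (logP > 3 and TPSA < 75), else ``intermediate``.

    Boundary values (logP exactly 3, TPSA exactly 75) fall to intermediate.
    """
    if profile.logp < 3 and profile.tpsa > 75:
        return "compliant"
    if profile.logp > 3 and profile.tpsa < 75:
        return "lipophilic"
    return "intermediate"


def physchem_table(mols: list[Molecule]) -> "pandas.DataFrame":  # noqa: F821
    """Descriptor table, one row per molecule, stable column order."""
    import pandas as pd

    rows = []
    for m in mols:
        p = compute_physchem(m)
        rows.append({
            "id": m.id, "smiles": m.smiles, "mw": round(p.mw, 3),
            "logp": round(p.logp, 3), "logs": round(p.logs, 3),
            "tpsa": round(p.tpsa, 2), "hbd": p.hbd, "hba": p.hba,
            "amides": p.amide_count, "rotatable_bonds": p.rotatable_bonds,
            "rule_3_75": classify_rule_3_75(p),
        })
    return pd.DataFrame(rows)
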