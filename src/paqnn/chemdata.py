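"""Compound curation, fingerprint similarity, and dataset-diversity analysis.

Curation follows the usual QSPR hygiene for an experimental
proton-affinity compilation: drop molecules with elements outside the
organic set {C, H, N, P, O, S}, drop radical species, and merge
stereoisomer groups whose PA values agree to within 1 kcal/mol (keeping
the mean), otherwise keep every stereoisomer.  Diversity is assessed with
Tanimoto similarity on circular (Morgan radius-2) fingerprints and
Butina sphere-exclusion clustering at a similarity cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "Fingerprint",
    "curate_records",
    "tanimoto",
    "butina_cluster",
    "diversity_summary",
    "DiversitySummary",
    "morgan_fingerprints",
    "maccs_fingerprints",
    "read_compounds_csv",
    "write_compounds_csv",
    "write_clusters_csv",
]

DEFAULT_ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "P", "O", "S"})

#: PA window (kcal/mol) within which a stereoisomer group is merged to its mean.
STEREO_MERGE_WINDOW = 1.0


@dataclass
class CompoundRecord:
    """One molecule: identifier, SMILES, experimental PA in kcal/mol."""

    id: str
    smiles: str
    pa: float
    is_radical: bool = False
    stereo_group_key: str | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not np.isfinite(self.pa):
            raise ValueError("pa must be finite")


@dataclass
class Fingerprint:
    """Fixed-length binary vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be a flat 0/1 vector")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return self.bits.shape[0]


def _as_bits(fp) -> np.ndarray:
    if isinstance(fp, Fingerprint):
        return fp.bits
    arr = np.asarray(fp, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("fingerprint must be a flat bit vector")
    return arr


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def _annotate(record: CompoundRecord, allowed_elements) -> CompoundRecord | None:
    """Parse the SMILES and fill radical/stereo-key fields.

    Returns None (with a logged reason) when the molecule is unparsable or
    contains a disallowed element.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        log.warning("rejecting %s: unparsable SMILES %r", record.id, record.smiles)
        return None
    elements = {atom.GetSymbol() for atom in mol.GetAtoms()}
    elements.add("H")  # implicit hydrogens
    bad = elements - set(allowed_elements)
    if bad:
        log.info("rejecting %s: disallowed elements %s", record.id, sorted(bad))
        return None
    is_radical = any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms())
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    key = Chem.MolToSmiles(flat)  # canonical, stereo-stripped
    return replace(record, is_radical=is_radical, stereo_group_key=key)


def curate_records(records, allowed_elements=DEFAULT_ALLOWED_ELEMENTS):
    """Apply the curation protocol; survivors keep their input order.

    Removes unparsable SMILES, molecules with elements outside
    ``allowed_elements``, and radicals.  Stereoisomers (same canonical
    structure once stereo descriptors are stripped) are merged to a single
    record with the mean PA when their PA spread is below 1 kcal/mol;
    otherwise all are kept.
    """
    annotated: list[CompoundRecord] = []
    for rec in records:
        ann = _annotate(rec, allowed_elements)
        if ann is None:
            continue
        if ann.is_radical:
            log.info("rejecting %s: radical species", ann.id)
            continue
        annotated.append(ann)

    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(annotated):
        groups.setdefault(rec.stereo_group_key, []).append(i)

    keep: dict[int, CompoundRecord] = {}
    for key, idxs in groups.items():
        pas = [annotated[i].pa for i in idxs]
        if len(idxs) > 1 and max(pas) - min(pas) < STEREO_MERGE_WINDOW:
            first = idxs[0]
            keep[first] = replace(annotated[first], pa=float(np.mean(pas)))
        else:
            for i in idxs:
                keep[i] = annotated[i]
    return [keep[i] for i in sorted(keep)]


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def tanimoto(a, b) -> float:
    """Tanimoto coefficient c / (a + b - c) on set-bit counts.

    Undefined (raises) when both fingerprints are all-zero.
    """
    A, B = _as_bits(a), _as_bits(b)
    if A.shape != B.shape:
        raise ValueError("fingerprints must have equal length")
    na, nb = int(A.sum()), int(B.sum())
    if na == 0 and nb == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    c = int(np.bitwise_and(A, B).sum())
    return c / (na + nb - c)


def _similarity_matrix(fps) -> np.ndarray:
    M = np.stack([_as_bits(f) for f in fps]).astype(np.int64)
    pop = M.sum(axis=1)
    if (pop == 0).any():
        raise ValueError("all-zero fingerprint has no defined similarity")
    inter = M @ M.T
    union = pop[:, None] + pop[None, :] - inter
    return inter / union


def butina_cluster(fps, cutoff: float = 0.7) -> np.ndarray:
    """Butina leader clustering; returns a cluster label per item.

    Neighbor lists are built at similarity >= ``cutoff``; the unassigned
    item with the most unassigned neighbors (ties: lowest input index)
    becomes the next centroid and absorbs its unassigned neighbors.
    Singletons come out as size-1 clusters.  Labels are dense integers in
    order of cluster creation.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    n = len(fps)
    if n == 0:
        return np.zeros(0, dtype=int)
    sim = _similarity_matrix(fps)
    neighbor = sim >= cutoff
    np.fill_diagonal(neighbor, False)

    labels = np.full(n, -1, dtype=int)
    next_label = 0
    unassigned = np.ones(n, dtype=bool)
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[centroid] & unassigned)
        labels[centroid] = next_label
        labels[members] = next_label
        unassigned[centroid] = False
        unassigned[members] = False
        next_label += 1
    return labels


@dataclass
class DiversitySummary:
    mean_similarity: float
    std_similarity: float
    n_singletons: int
    n_multi_clusters: int
    largest_cluster_size: int
    n_clusters: int


def diversity_summary(fps, cutoff: float = 0.7) -> DiversitySummary:
    """Pairwise-similarity statistics plus Butina cluster composition."""
    n = len(fps)
    if n < 2:
        raise ValueError("need at least 2 fingerprints")
    sim = _similarity_matrix(fps)
    iu = np.triu_indices(n, k=1)
    pairs = sim[iu]
    labels = butina_cluster(fps, cutoff=cutoff)
    sizes = np.bincount(labels)
    return DiversitySummary(
        mean_similarity=float(pairs.mean()),
        std_similarity=float(pairs.std()),
        n_singletons=int((sizes == 1).sum()),
        n_multi_clusters=int((sizes > 1).sum()),
        largest_cluster_size=int(sizes.max()),
        n_clusters=int(sizes.size),
    )


# ---------------------------------------------------------------------------
# fingerprint generation from SMILES (rdkit)
# ---------------------------------------------------------------------------

def morgan_fingerprints(smiles_list, radius: int = 2, n_bits: int = 2048):
    """Hashed circular (Morgan radius-2) fingerprints for diversity analysis."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smi!r}")
        out.append(Fingerprint(np.array(gen.GetFingerprint(mol), dtype=np.uint8)))
    return out


def maccs_fingerprints(smiles_list):
    """167-bit MACCS substructure-key fingerprints (feature columns)."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    out = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smi!r}")
        out.append(Fingerprint(np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.uint8)))
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_compounds_csv(path) -> list[CompoundRecord]:
    """Columns: id, smiles, pa."""
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    return [
        CompoundRecord(id=row.id, smiles=row.smiles, pa=float(row.pa))
        for row in df.itertuples(index=False)
    ]


def write_compounds_csv(records, path) -> None:
    pd.DataFrame(
        {"id": [r.id for r in records], "smiles": [r.smiles for r in records],
         "pa": [r.pa for r in records]}
    ).to_csv(path, index=False)


def write_clusters_csv(ids, labels, path) -> None:
    pd.DataFrame({"id": list(ids), "cluster": np.asarray(labels)}).to_csv(
        path, index=False
    )
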