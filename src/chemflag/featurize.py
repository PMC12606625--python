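"""Structure standardization and the four feature representations.

Representations: the RDKit 2-D descriptor panel, MACCS keys (with a
configurable exclusion list), 1024-bit ECFP4 fingerprints, and
custom-fragment fingerprints built from a multi-method fragment catalog
(Bemis-Murcko, RECAP, BRICS, ring detachment). Also implements the ECFP4
bit-collision analysis: folding a sparse set of atom-environment
identifiers to a fixed bit length maps distinct environments onto shared
bits, and the collision statistic quantifies how that grows with library
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, MACCSkeys
from rdkit.Chem import BRICS, Recap
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats

from .containers import FeatureMatrix

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

FRAGMENT_METHODS = ("bemis_murcko", "recap", "brics", "ring_detach")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> str:
    """Canonical standardized SMILES: largest organic fragment, neutralized.

    Idempotent; raises ``ValueError`` on unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def _as_mols(molecules) -> list[Chem.Mol]:
    out = []
    for m in molecules:
        if isinstance(m, Chem.Mol):
            out.append(m)
        else:
            mol = Chem.MolFromSmiles(m)
            if mol is None:
                raise ValueError(f"unparseable SMILES: {m!r}")
            out.append(mol)
    return out


# ---------------------------------------------------------------------------
# Descriptor panel
# ---------------------------------------------------------------------------

def descriptor_panel_names() -> list[str]:
    """Names of the default 2-D descriptor panel (the toolkit's full list)."""
    return [name for name, _ in Descriptors._descList]


def compute_descriptor_panel(
    molecules, molecule_ids=None, category_map: dict | None = None
) -> FeatureMatrix:
    """Full default 2-D descriptor panel, one column per descriptor.

    Descriptor failures and non-finite values are recorded as NaN and
    logged; impute them with :func:`impute_nonfinite` using training-split
    statistics before modelling.
    """
    mols = _as_mols(molecules)
    ids = [str(i) for i in molecule_ids] if molecule_ids is not None else [f"m{i}" for i in range(len(mols))]
    names = descriptor_panel_names()
    values = np.full((len(mols), len(names)), np.nan)
    for i, mol in enumerate(mols):
        calc = Descriptors.CalcMolDescriptors(mol)
        for j, name in enumerate(names):
            v = calc.get(name)
            try:
                v = float(v)
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                logger.warning("non-finite descriptor %s for molecule %s", name, ids[i])
                v = np.nan
            values[i, j] = v
    metadata = {"category": category_map or {}}
    return FeatureMatrix(ids, names, values, kind="descriptor_panel", metadata=metadata)


def impute_nonfinite(matrix: FeatureMatrix, train_ids: list[str]) -> FeatureMatrix:
    """Replace NaNs by the column median computed on ``train_ids`` only."""
    df = matrix.to_dataframe()
    med = df.loc[[str(i) for i in train_ids]].median(axis=0)
    filled = df.fillna(med).fillna(0.0)
    return FeatureMatrix.from_dataframe(filled, kind=matrix.kind, metadata=matrix.metadata)


# ---------------------------------------------------------------------------
# MACCS and ECFP4
# ---------------------------------------------------------------------------

def compute_maccs(molecules, molecule_ids=None, excluded_keys=()) -> FeatureMatrix:
    """166-key MACCS matrix minus ``excluded_keys`` (1-based key indices)."""
    excluded = sorted(set(int(k) for k in excluded_keys))
    for k in excluded:
        if not 1 <= k <= 166:
            raise ValueError(f"invalid MACCS key index {k}")
    mols = _as_mols(molecules)
    ids = [str(i) for i in molecule_ids] if molecule_ids is not None else [f"m{i}" for i in range(len(mols))]
    keep = [k for k in range(1, 167) if k not in excluded]
    values = np.zeros((len(mols), len(keep)))
    for i, mol in enumerate(mols):
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        on = set(fp.GetOnBits())
        values[i] = [1.0 if k in on else 0.0 for k in keep]
    return FeatureMatrix(ids, [f"MACCS_{k}" for k in keep], values, kind="maccs",
                         metadata={"excluded_keys": excluded})


def compute_ecfp4(molecules, molecule_ids=None, n_bits: int = 1024) -> FeatureMatrix:
    """Radius-2 circular fingerprints folded to ``n_bits`` (power of two >= 64)."""
    if n_bits < 64 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError("n_bits must be a power of two >= 64")
    mols = _as_mols(molecules)
    ids = [str(i) for i in molecule_ids] if molecule_ids is not None else [f"m{i}" for i in range(len(mols))]
    gen = AllChem.GetMorganGenerator(radius=2, fpSize=n_bits)
    values = np.zeros((len(mols), n_bits))
    for i, mol in enumerate(mols):
        values[i] = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=float)
    return FeatureMatrix(ids, [f"ECFP4_{b}" for b in range(n_bits)], values, kind="ecfp4")


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of fused ring systems (rings sharing atoms merged)."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            ring |= s
            systems.remove(s)
        systems.append(ring)
    return systems


def _ring_detach_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    """Isolate each fused ring system, wildcard atoms at attachment points."""
    frags = []
    for system in _ring_systems(mol):
        em = Chem.RWMol(mol)
        # replace first-shell neighbours by dummies, then drop the rest
        attach = set()
        for idx in system:
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() not in system:
                    attach.add(nb.GetIdx())
        for idx in attach:
            a = em.GetAtomWithIdx(idx)
            a.SetAtomicNum(0)
            a.SetFormalCharge(0)
            a.SetNoImplicit(True)
            a.SetNumExplicitHs(0)
            a.SetIsAromatic(False)
            for b in a.GetBonds():
                if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
                    b.SetBondType(Chem.BondType.SINGLE)
                    b.SetIsAromatic(False)
        keep = system | attach
        for idx in sorted(range(mol.GetNumAtoms()), reverse=True):
            if idx not in keep:
                em.RemoveAtom(idx)
        frag = em.GetMol()
        try:
            Chem.SanitizeMol(frag)
            frags.append(frag)
        except Exception:  # pragma: no cover - malformed intermediate
            continue
    return frags


def fragment_molecule(molecule, methods=frozenset(FRAGMENT_METHODS)) -> set[str]:
    """Union of SMARTS fragments from the requested methods.

    Bemis-Murcko contributes the scaffold; RECAP and BRICS their recursive
    retrosynthetic leaves; ring detachment each fused ring system with
    wildcard attachment points. A method yielding nothing (e.g. Murcko on an
    acyclic molecule) contributes an empty set. Aromaticity, connectivity
    and stereochemistry are preserved in the emitted patterns.
    """
    (mol,) = _as_mols([molecule])
    unknown = set(methods) - set(FRAGMENT_METHODS)
    if unknown:
        raise ValueError(f"unknown fragmentation methods: {sorted(unknown)}")
    frag_mols: list[Chem.Mol] = []
    if "bemis_murcko" in methods:
        scaf = MurckoScaffold.GetScaffoldForMol(mol)
        if scaf is not None and scaf.GetNumAtoms() > 0:
            frag_mols.append(scaf)
    if "recap" in methods:
        tree = Recap.RecapDecompose(mol)
        for leaf in tree.GetLeaves().values():
            frag_mols.append(leaf.mol)
    if "brics" in methods:
        for smi in BRICS.BRICSDecompose(mol):
            m = Chem.MolFromSmiles(smi)
            if m is not None:
                frag_mols.append(m)
    if "ring_detach" in methods:
        frag_mols.extend(_ring_detach_fragments(mol))

    patterns: set[str] = set()
    for fm in frag_mols:
        # strip RECAP/BRICS link-atom labels so dummies act as pure wildcards
        fm = Chem.RWMol(fm)
        for atom in fm.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetIsotope(0)
                atom.SetAtomMapNum(0)
        fm = fm.GetMol()
        if fm.GetNumAtoms() == 0:
            continue
        # attachment dummies become wildcard queries: the fragment matches
        # any substituted parent at that position
        patterns.add(Chem.MolToSmarts(fm).replace("[#0]", "[*]"))
    return patterns


@dataclass
class FragmentCatalog:
    """Curated SMARTS fragment catalog with per-pattern library prevalence."""

    patterns: list[str]
    counts: list[int]
    sources: list[set] = field(default_factory=list)
    min_count: int = 1

    def __post_init__(self) -> None:
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("duplicate patterns in catalog")
        for p in self.patterns:
            if Chem.MolFromSmarts(p) is None:
                raise ValueError(f"invalid SMARTS in catalog: {p!r}")
        if any(c < self.min_count for c in self.counts):
            raise ValueError("catalog contains patterns below min_count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pattern": self.patterns, "count": self.counts,
                             "sources": [",".join(sorted(s)) for s in self.sources]})


def count_matching_molecules(pattern: str, mols: list[Chem.Mol]) -> int:
    """Number of distinct molecules containing ``pattern`` as a substructure."""
    q = Chem.MolFromSmarts(pattern)
    if q is None:
        raise ValueError(f"invalid SMARTS: {pattern!r}")
    return sum(1 for m in mols if m.HasSubstructMatch(q))


def build_fragment_catalog(
    library, methods=frozenset(FRAGMENT_METHODS), min_count: int = 20
) -> FragmentCatalog:
    """Fragment every library molecule, pool unique patterns, keep those whose
    substructure-match prevalence reaches ``min_count`` molecules.

    Sorted by descending count then pattern text.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not methods:
        return FragmentCatalog(patterns=[], counts=[], sources=[], min_count=min_count)
    mols = _as_mols(library)
    if not mols:
        raise ValueError("empty library")
    origin: dict[str, set] = {}
    for mol in mols:
        for method in methods:
            for p in fragment_molecule(mol, methods={method}):
                origin.setdefault(p, set()).add(method)
    kept = []
    for p in origin:
        c = count_matching_molecules(p, mols)
        if c >= min_count:
            kept.append((p, c))
    kept.sort(key=lambda t: (-t[1], t[0]))
    return FragmentCatalog(
        patterns=[p for p, _ in kept],
        counts=[c for _, c in kept],
        sources=[origin[p] for p, _ in kept],
        min_count=min_count,
    )


def custom_fragment_fingerprint(molecules, catalog: FragmentCatalog, molecule_ids=None) -> FeatureMatrix:
    """Bit i of molecule m is 1 iff catalog pattern i matches m."""
    if not catalog.patterns:
        raise ValueError("empty fragment catalog")
    queries = [Chem.MolFromSmarts(p) for p in catalog.patterns]
    mols = _as_mols(molecules)
    ids = [str(i) for i in molecule_ids] if molecule_ids is not None else [f"m{i}" for i in range(len(mols))]
    values = np.zeros((len(mols), len(queries)))
    for i, mol in enumerate(mols):
        for j, q in enumerate(queries):
            values[i, j] = 1.0 if mol.HasSubstructMatch(q) else 0.0
    return FeatureMatrix(ids, [f"FRAG_{j}" for j in range(len(queries))], values,
                         kind="custom_fragment", metadata={"patterns": list(catalog.patterns)})


# ---------------------------------------------------------------------------
# Bit-collision analysis
# ---------------------------------------------------------------------------

@dataclass
class CollisionCurve:
    fractions: list[float]
    n_sampled: list[int]
    mean_collisions: list[float]
    sd_collisions: list[float]
    n_repeats: int
    n_bits: int
    seed: int
    statistic: str = "colliding_bits"

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if not (np.all(np.diff(f) > 0) and np.all((f > 0) & (f <= 1))):
            raise ValueError("fractions must be strictly increasing in (0, 1]")
        if not len(self.fractions) == len(self.n_sampled) == len(self.mean_collisions) == len(self.sd_collisions):
            raise ValueError("inconsistent curve lengths")
        if any(s < 0 for s in self.sd_collisions):
            raise ValueError("sd must be >= 0")


def unfolded_identifiers(mol: Chem.Mol, radius: int = 2) -> set[int]:
    """Distinct unfolded Morgan atom-environment identifiers of a molecule."""
    gen = AllChem.GetMorganGenerator(radius=radius)
    return set(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def collision_statistic(identifiers: set[int], n_bits: int, statistic: str = "colliding_bits") -> int:
    """Collision statistic of an identifier set folded modulo ``n_bits``.

    ``colliding_bits`` (default): number of folded bits mapped to by >= 2
    distinct identifiers. ``excess_identifiers``: #identifiers - #occupied
    bits (total collisions rather than affected bits).
    """
    bits: dict[int, int] = {}
    for ident in identifiers:
        b = ident % n_bits
        bits[b] = bits.get(b, 0) + 1
    if statistic == "colliding_bits":
        return sum(1 for c in bits.values() if c >= 2)
    if statistic == "excess_identifiers":
        return len(identifiers) - len(bits)
    raise ValueError(f"unknown collision statistic {statistic!r}")


def bit_collision_analysis(
    library,
    labels,
    fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    n_repeats: int = 10,
    n_bits: int = 1024,
    seed: int = 0,
    statistic: str = "colliding_bits",
) -> CollisionCurve:
    """Collision statistic vs stratified sample size.

    For each fraction, ``n_repeats`` stratified samples (preserving the
    active/inactive balance) are drawn; the union of the sampled molecules'
    unfolded identifiers is folded to ``n_bits`` and the collision statistic
    evaluated. At fraction 1.0 the sample is the full library so the sd is 0
    under the default statistic.
    """
    fractions = sorted(float(f) for f in fractions)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    mols = _as_mols(library)
    labels = np.asarray(labels)
    per_mol_ids = [unfolded_identifiers(m) for m in mols]
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)

    ns, means, sds = [], [], []
    for frac in fractions:
        vals = []
        n_taken = None
        for _ in range(n_repeats):
            take_idx: list[int] = []
            for cls in classes:
                idx = np.flatnonzero(labels == cls)
                k = max(1, int(round(frac * len(idx))))
                take_idx.extend(rng.choice(idx, size=min(k, len(idx)), replace=False))
            n_taken = len(take_idx)
            ids: set[int] = set()
            for i in take_idx:
                ids |= per_mol_ids[i]
            vals.append(collision_statistic(ids, n_bits, statistic))
        ns.append(int(n_taken))
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals)))
    return CollisionCurve(fractions=list(fractions), n_sampled=ns, mean_collisions=means,
                          sd_collisions=sds, n_repeats=n_repeats, n_bits=n_bits,
                          seed=seed, statistic=statistic)


def collision_size_correlation(curves: list[CollisionCurve]):
    """Pearson and Spearman correlation of sampled-set size vs mean collisions.

    Pools the (n_sampled, mean_collisions) points of all curves; requires at
    least three points and non-constant inputs.
    """
    xs, ys = [], []
    for c in curves:
        xs.extend(c.n_sampled)
        ys.extend(c.mean_collisions)
    if len(xs) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        raise ValueError("correlation undefined for constant input")
    pr = stats.pearsonr(xs, ys)
    sr = stats.spearmanr(xs, ys)
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue)}
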