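"""Synthetic fixtures: toy molecule libraries, assay-record tables, and
clustered feature worlds with planted boundary compounds.

The feature-world generator emulates the statistical structure the flagging
method assumes: within each scaffold-like cluster, active and inactive
compounds occupy disjoint per-feature value intervals separated by a gap,
and a planted fraction of "boundary" compounds carries ``k_opposite``
features drawn from the opposite class's interval. Boundary compounds are
the synthetic analogue of molecules near a model's decision boundary whose
feature values fall in the range typically occupied by the opposite class —
exactly the population the opposite-range flagging rules are designed to
catch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix


@dataclass
class FeatureWorldSpec:
    """Parameters of a clustered two-class feature world.

    ``class_separation`` is the gap (in feature units) between the active
    and inactive intervals of every (cluster, feature) pair; intervals have
    unit width. ``boundary_fraction`` of compounds are boundary compounds
    with ``k_opposite`` randomly chosen features sampled from the opposite
    class's interval. Gaussian noise with sd ``noise_sd`` is added on top.
    """

    n_clusters: int = 12
    molecules_per_cluster: int = 30
    n_features: int = 40
    class_separation: float = 0.25
    boundary_fraction: float = 0.15
    k_opposite: int = 10
    noise_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.boundary_fraction < 1.0:
            raise ValueError("boundary_fraction must be in [0, 1)")
        if self.k_opposite > self.n_features:
            raise ValueError("k_opposite cannot exceed n_features")
        if self.boundary_fraction > 0 and self.class_separation <= 0:
            raise ValueError(
                "boundary compounds require a positive class_separation gap"
            )


@dataclass
class FeatureWorld:
    """A generated world plus its ground-truth manifest."""

    spec: FeatureWorldSpec
    features: FeatureMatrix
    labels: np.ndarray           # 1 = active, 0 = inactive (true class)
    cluster_ids: np.ndarray      # int cluster per molecule
    boundary_mask: np.ndarray    # True where the compound was planted as boundary
    # interval bounds, shape (n_clusters, n_features, 2): [:, :, 0]=lo, [:, :, 1]=hi
    active_intervals: np.ndarray = field(repr=False, default=None)
    inactive_intervals: np.ndarray = field(repr=False, default=None)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.features.molecule_ids,
                "label": np.where(self.labels == 1, "active", "inactive"),
                "cluster_id": self.cluster_ids,
                "is_boundary": self.boundary_mask,
            }
        )


def generate_feature_world(spec: FeatureWorldSpec) -> FeatureWorld:
    """Generate a clustered feature world per ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    width = 1.0
    # per (cluster, feature): base offset and which class sits low
    base = rng.uniform(0.0, 10.0, size=(spec.n_clusters, spec.n_features))
    active_low = rng.random(size=(spec.n_clusters, spec.n_features)) < 0.5

    lo_iv = np.stack([base, base + width], axis=-1)
    hi_iv = np.stack(
        [base + width + spec.class_separation, base + 2 * width + spec.class_separation],
        axis=-1,
    )
    active_iv = np.where(active_low[..., None], lo_iv, hi_iv)
    inactive_iv = np.where(active_low[..., None], hi_iv, lo_iv)

    n = spec.n_clusters * spec.molecules_per_cluster
    cluster_ids = np.repeat(np.arange(spec.n_clusters), spec.molecules_per_cluster)
    # balanced classes within every cluster
    half = spec.molecules_per_cluster // 2
    labels = np.concatenate(
        [
            np.concatenate(
                [np.ones(spec.molecules_per_cluster - half, dtype=int), np.zeros(half, dtype=int)]
            )
            for _ in range(spec.n_clusters)
        ]
    )
    boundary_mask = rng.random(n) < spec.boundary_fraction

    values = np.empty((n, spec.n_features))
    for i in range(n):
        c, y = cluster_ids[i], labels[i]
        own = active_iv[c] if y == 1 else inactive_iv[c]
        opp = inactive_iv[c] if y == 1 else active_iv[c]
        u = rng.random(spec.n_features)
        values[i] = own[:, 0] + u * (own[:, 1] - own[:, 0])
        if boundary_mask[i]:
            flip = rng.choice(spec.n_features, size=spec.k_opposite, replace=False)
            u2 = rng.random(spec.k_opposite)
            values[i, flip] = opp[flip, 0] + u2 * (opp[flip, 1] - opp[flip, 0])
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    fm = FeatureMatrix(
        molecule_ids=[f"mol_{i:04d}" for i in range(n)],
        feature_names=[f"feat_{j:03d}" for j in range(spec.n_features)],
        values=values,
        kind="synthetic",
    )
    return FeatureWorld(
        spec=spec,
        features=fm,
        labels=labels,
        cluster_ids=cluster_ids,
        boundary_mask=boundary_mask,
        active_intervals=active_iv,
        inactive_intervals=inactive_iv,
    )


# ---------------------------------------------------------------------------
# Toy molecule library
# ---------------------------------------------------------------------------

_RING_SCAFFOLDS = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "C1CCNCC1",        # piperidine
    "C1CCOCC1",        # tetrahydropyran
    "C1CCCCC1",        # cyclohexane
    "c1cc2ccccc2[nH]1",  # indole
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
]

_SUBSTITUENTS = [
    "", "C", "CC", "CCC", "CCO", "CO", "C(=O)O", "C(=O)N", "CN", "N",
    "O", "OC", "Cl", "Br", "F", "C(F)(F)F", "S(=O)(=O)N", "C#N",
]

_CHAINS = [
    "CCCCC", "CCOCC", "CCNCC", "CC(=O)OCC", "CCCC(=O)O", "CCCCN",
    "CC(C)CC(=O)O", "CCSCC",
]

_SALT_FORMS = [
    "CC(=O)[O-].[Na+]",
    "C[NH3+].[Cl-]",
    "OC(=O)c1ccccc1.[Na+].[OH-]",
    "CC[NH2+]CC.[Br-]",
    "[K+].[O-]C(=O)CCN",
]


def generate_toy_library(n: int, seed: int = 0) -> list[str]:
    """Deterministic list of ``n`` valid, diverse SMILES.

    Built from substituted ring scaffolds and acyclic chains; a few salt
    forms and charged species are interleaved to exercise standardization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    combos = [
        f"{sub}{scaf}" if sub else scaf
        for scaf, sub in itertools.product(_RING_SCAFFOLDS, _SUBSTITUENTS)
    ]
    combos += _CHAINS
    pool = [s for s in combos if Chem.MolFromSmiles(s) is not None]
    out: list[str] = []
    while len(out) < n:
        if len(out) % 17 == 13:  # sprinkle salts/charged forms
            out.append(_SALT_FORMS[int(rng.integers(len(_SALT_FORMS)))])
        else:
            out.append(pool[int(rng.integers(len(pool)))])
    return out[:n]


# ---------------------------------------------------------------------------
# ChEMBL-like activity-record tables
# ---------------------------------------------------------------------------

_GOOD = dict(
    standard_type="IC50",
    standard_relation="=",
    standard_unit="nM",
    target_type="CELL-LINE",
    target_organism="Human",
    assay_type="F",
    assay_organism="Homo sapiens",
    bao_label="Cell-based format",
    assay_description="Antiproliferative activity after 72 h by MTT assay",
)

# one deliberate violation per curation criterion, keyed by criterion name
_VIOLATIONS = {
    "standard_type": dict(standard_type="Ki"),
    "standard_relation": dict(standard_relation="~"),
    "standard_unit": dict(standard_unit="uM"),
    "target_type": dict(target_type="SINGLE PROTEIN"),
    "target_organism": dict(target_organism="Rattus norvegicus"),
    "assay_type": dict(assay_type="B"),
    "assay_organism": dict(assay_organism="Mus musculus"),
    "bao_label": dict(bao_label="assay format"),
    "assay_description": dict(assay_description="Inhibition measured by ELISA"),
}


def generate_activity_records(n: int, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Activity-record table with a ground-truth curation manifest.

    Returns ``(records, manifest)``. The manifest is constructed first and
    the records are materialised from it, so every downstream curation
    assertion (filter pass set, deduplication winner, label) can reference
    the manifest rather than re-deriving expectations. The table contains,
    by construction: records passing all nine filters, one failure case per
    criterion, duplicate groups whose weighted-average-closest member is
    known, percent-inhibition-only inactives, and a malformed record.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    rng = np.random.default_rng(seed)
    # unique structures so deduplication groups coincide with compounds
    seen: set[str] = set()
    smiles_pool = []
    for s in generate_toy_library(4 * n + 200, seed=seed + 1):
        if s not in seen:
            seen.add(s)
            smiles_pool.append(s)

    rows: list[dict] = []
    manifest: list[dict] = []
    fail_cycle = itertools.cycle(_VIOLATIONS)
    compound_counter = itertools.count()

    def new_compound() -> tuple[str, str]:
        i = next(compound_counter)
        return f"CPD{i:05d}", smiles_pool[i % len(smiles_pool)]

    i = 0
    while i < n:
        kind = i % 6
        cid, smi = new_compound()
        if kind in (0, 1):  # clean passing record, value drawn around threshold
            value = float(rng.choice([200.0, 900.0, 5_000.0, 9_000.0, 12_000.0, 40_000.0]))
            rows.append(dict(_GOOD, compound_id=cid, smiles=smi,
                             standard_value=value, percent_inhibition=np.nan,
                             test_concentration=np.nan))
            manifest.append(dict(compound_id=cid, record_index=len(rows) - 1,
                                 expected_pass=True, fail_criterion="",
                                 dedup_group="", dedup_winner=False,
                                 expected_label="active" if value <= 10_000 else "inactive"))
            i += 1
        elif kind == 2:  # single-criterion failure
            crit = next(fail_cycle)
            rec = dict(_GOOD, **_VIOLATIONS[crit], compound_id=cid, smiles=smi,
                       standard_value=float(rng.choice([100.0, 20_000.0])),
                       percent_inhibition=np.nan, test_concentration=np.nan)
            rows.append(rec)
            manifest.append(dict(compound_id=cid, record_index=len(rows) - 1,
                                 expected_pass=False, fail_criterion=crit,
                                 dedup_group="", dedup_winner=False,
                                 expected_label=""))
            i += 1
        elif kind == 3:  # duplicate trio with a unique closest-to-average member
            lo = float(rng.choice([100.0, 300.0, 700.0]))
            values = [lo, lo * 2, lo * 9]  # mean = 4*lo, closest is lo*2, unique
            group = f"G{cid}"
            for j, v in enumerate(values):
                rows.append(dict(_GOOD, compound_id=cid, smiles=smi,
                                 standard_value=v, percent_inhibition=np.nan,
                                 test_concentration=np.nan))
                manifest.append(dict(compound_id=cid, record_index=len(rows) - 1,
                                     expected_pass=True, fail_criterion="",
                                     dedup_group=group, dedup_winner=(j == 1),
                                     expected_label="active" if lo * 2 <= 10_000 else "inactive"))
            i += 1
        elif kind == 4:  # percent-inhibition-only inactive at 10 uM
            pct = float(rng.uniform(5.0, 45.0))
            rows.append(dict(_GOOD, compound_id=cid, smiles=smi,
                             standard_value=np.nan, percent_inhibition=pct,
                             test_concentration=10.0))
            manifest.append(dict(compound_id=cid, record_index=len(rows) - 1,
                                 expected_pass=True, fail_criterion="",
                                 dedup_group="", dedup_winner=False,
                                 expected_label="inactive"))
            i += 1
        else:  # malformed record: mandatory field missing
            rows.append(dict(_GOOD, compound_id=cid, smiles=smi,
                             standard_value=np.nan, percent_inhibition=np.nan,
                             test_concentration=np.nan, standard_type=None))
            manifest.append(dict(compound_id=cid, record_index=len(rows) - 1,
                                 expected_pass=False, fail_criterion="malformed",
                                 dedup_group="", dedup_winner=False,
                                 expected_label=""))
            i += 1

    records = pd.DataFrame(rows)
    return records, pd.DataFrame(manifest)
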