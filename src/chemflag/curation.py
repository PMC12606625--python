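"""Curation of activity-annotated compound tables.

Implements the nine-criterion assay filter, weighted-average deduplication,
10 uM activity labeling (with percent-inhibition augmentation of the
inactive class), and a diversity-preserving stratified 70:30 split.

Tables are plain pandas DataFrames with the ActivityRecord columns::

    compound_id, smiles, standard_type, standard_relation, standard_value,
    standard_unit, target_type, target_organism, assay_type, assay_organism,
    bao_label, assay_description, percent_inhibition, test_concentration

``standard_value`` is in nM; ``test_concentration`` in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANDATORY_FIELDS = [
    "compound_id", "smiles", "standard_type", "standard_relation",
    "standard_unit", "target_type", "target_organism", "assay_type",
    "assay_organism", "bao_label", "assay_description",
]

DEFAULT_DURATION_TOKENS = ["24 h", "48 h", "72 h", "96 h", "24h", "48h", "72h", "96h"]
DEFAULT_METHOD_TOKENS = ["MTT", "SRB", "MTS", "CCK8"]


@dataclass
class FilterCriteria:
    """The nine assay-curation criteria; any set to None is skipped."""

    standard_types: tuple = ("IC50", "GI50", "EC50", "ED50")
    standard_relations: tuple = ("=", ">", "<")
    standard_unit: str = "nM"
    target_type: str = "CELL-LINE"
    target_organism: str = "Human"
    assay_type: str = "F"
    assay_organism: str = "Homo sapiens"
    bao_label: str = "Cell-based format"
    duration_tokens: list = field(default_factory=lambda: list(DEFAULT_DURATION_TOKENS))
    method_tokens: list = field(default_factory=lambda: list(DEFAULT_METHOD_TOKENS))


def _description_ok(desc: str, criteria: FilterCriteria) -> bool:
    low = str(desc).lower()
    has_duration = any(t.lower() in low for t in criteria.duration_tokens)
    has_method = any(t.lower() in low for t in criteria.method_tokens)
    return has_duration and has_method


def _first_failure(row: pd.Series, criteria: FilterCriteria) -> str:
    """Name of the first failing criterion, or '' if the record passes.

    Criteria are checked in the fixed order (i)-(ix). Percent-inhibition-only
    records (no concentration-response value) skip the value-bound criteria
    (type, relation, unit) — they enter the pipeline solely to augment the
    inactive class at labeling time.
    """
    for f in MANDATORY_FIELDS:
        v = row.get(f)
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return "malformed"
    has_value = pd.notna(row.get("standard_value"))
    has_pct = pd.notna(row.get("percent_inhibition"))
    if not has_value and not has_pct:
        return "malformed"
    if has_value and float(row["standard_value"]) < 0:
        return "malformed"

    if has_value:
        if criteria.standard_types is not None and row["standard_type"] not in criteria.standard_types:
            return "standard_type"
        if criteria.standard_relations is not None and row["standard_relation"] not in criteria.standard_relations:
            return "standard_relation"
        if criteria.standard_unit is not None and row["standard_unit"] != criteria.standard_unit:
            return "standard_unit"
    if criteria.target_type is not None and row["target_type"] != criteria.target_type:
        return "target_type"
    if criteria.target_organism is not None and row["target_organism"] != criteria.target_organism:
        return "target_organism"
    if criteria.assay_type is not None and row["assay_type"] != criteria.assay_type:
        return "assay_type"
    if criteria.assay_organism is not None and row["assay_organism"] != criteria.assay_organism:
        return "assay_organism"
    if criteria.bao_label is not None and row["bao_label"] != criteria.bao_label:
        return "bao_label"
    if criteria.duration_tokens is not None and not _description_ok(row["assay_description"], criteria):
        return "assay_description"
    return ""


def filter_activity_records(
    records: pd.DataFrame, criteria: FilterCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the nine curation criteria.

    Returns ``(kept, rejection_log)``; ``kept`` preserves input order, the
    log has one row per rejected record with the first failing criterion
    (malformed records are rejected with an explicit ``malformed`` reason,
    never silently dropped).
    """
    criteria = criteria or FilterCriteria()
    if records.empty:
        return records.copy(), pd.DataFrame(columns=["record_index", "compound_id", "reason"])
    reasons = records.apply(_first_failure, axis=1, args=(criteria,))
    kept = records.loc[reasons == ""].copy()
    log = pd.DataFrame(
        {
            "record_index": records.index[reasons != ""],
            "compound_id": records.loc[reasons != "", "compound_id"].to_numpy(),
            "reason": reasons[reasons != ""].to_numpy(),
        }
    )
    return kept, log


def deduplicate_records(group: pd.DataFrame, weights: np.ndarray | None = None) -> pd.Series:
    """Pick the single record whose value is closest to the weighted average.

    ``weights`` default to equal. Ties break to the lower activity value,
    then to stable input order. Records without a concentration-response
    value (percent-inhibition-only) cannot be averaged; if the whole group
    lacks values the first record is returned.
    """
    if len(group) == 0:
        raise ValueError("empty duplicate group")
    valued = group[pd.notna(group["standard_value"])]
    if len(valued) == 0:
        return group.iloc[0]
    vals = valued["standard_value"].to_numpy(dtype=float)
    if weights is None:
        w = np.ones(len(vals))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(vals):
            raise ValueError("weights length mismatch")
    avg = float(np.average(vals, weights=w))
    dist = np.abs(vals - avg)
    best = np.lexsort((np.arange(len(vals)), vals, dist))[0]
    return valued.iloc[best]


def deduplicate(records: pd.DataFrame, key: str = "smiles", weights=None) -> pd.DataFrame:
    """One record per distinct ``key`` (standardized structure), chosen by
    :func:`deduplicate_records`."""
    out = [deduplicate_records(g, weights) for _, g in records.groupby(key, sort=False)]
    return pd.DataFrame(out).reset_index(drop=True)


def assign_labels(records: pd.DataFrame, threshold_nM: float = 10_000.0) -> pd.DataFrame:
    """Label curated records active/inactive at the activity threshold.

    Rules (threshold default 10 uM = 10,000 nM):

    * ``activity > threshold`` -> inactive; ``activity <= threshold`` -> active
      (values strictly above the threshold are inactive, so exactly 10,000 nM
      is active);
    * censored relations: ``>`` with value above threshold -> inactive, ``>``
      below threshold -> discarded as uninformative; symmetrically ``<`` with
      value at/below threshold -> active, ``<`` above threshold -> discarded;
    * percent-inhibition < 50% at 10 uM with no concentration-response value
      -> inactive (augments the inactive class); >= 50% without a value is
      uninformative and discarded.

    Returns a MoleculeRecord table (molecule_id, smiles, activity_nM, label).
    Records with neither annotation raise, listing the offending ids.
    """
    has_value = pd.notna(records.get("standard_value"))
    has_pct = pd.notna(records.get("percent_inhibition"))
    bad = records.loc[~has_value & ~has_pct, "compound_id"].tolist()
    if bad:
        raise ValueError(f"records with neither activity nor percent-inhibition: {bad}")

    out = []
    for _, row in records.iterrows():
        if pd.notna(row.get("standard_value")):
            v = float(row["standard_value"])
            rel = str(row.get("standard_relation", "="))
            if rel == ">" and v <= threshold_nM:
                continue  # censored below threshold: uninformative
            if rel == "<" and v > threshold_nM:
                continue
            label = "inactive" if v > threshold_nM else "active"
            out.append(dict(molecule_id=row["compound_id"], smiles=row["smiles"],
                            activity_nM=v, label=label))
        else:
            pct = float(row["percent_inhibition"])
            if pct < 50.0:
                out.append(dict(molecule_id=row["compound_id"], smiles=row["smiles"],
                                activity_nM=np.nan, label="inactive"))
            # >= 50% inhibition without a dose-response value: discarded
    return pd.DataFrame(out, columns=["molecule_id", "smiles", "activity_nM", "label"])


@dataclass
class SplitAssignment:
    train_ids: list[str]
    test_ids: list[str]
    ratio: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def _murcko_groups(smiles: list[str]) -> list[str]:
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    groups = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            groups.append("__invalid__")
            continue
        scaf = MurckoScaffold.GetScaffoldForMol(mol)
        smi = Chem.MolToSmiles(scaf) if scaf is not None else ""
        groups.append(smi if smi else "__acyclic__")
    return groups


def split_train_test(
    molecules: pd.DataFrame,
    ratio: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
    groups: list[str] | None = None,
) -> SplitAssignment:
    """Diversity-preserving stratified split.

    Within each activity class, molecules are grouped by Bemis-Murcko
    scaffold (or caller-supplied ``groups``) and each group contributes to
    the test set proportionally (largest-remainder apportionment), so both
    the class balance and the per-class scaffold diversity are preserved.
    Deterministic given ``seed``; per-class test counts land within one
    compound of the target ratio.
    """
    if len(molecules) < 10:
        raise ValueError("split not meaningful for fewer than 10 molecules")
    labels = molecules["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both activity classes required for a stratified split")
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError("ratio fractions must sum to 1")

    if groups is None:
        groups = _murcko_groups(molecules["smiles"].tolist())
    groups = np.asarray(groups)
    ids = molecules["molecule_id"].astype(str).to_numpy()
    rng = np.random.default_rng(seed)

    test_ids: list[str] = []
    train_ids: list[str] = []
    for cls in np.unique(labels):
        mask = labels == cls
        cls_ids, cls_groups = ids[mask], groups[mask]
        n_cls = int(mask.sum())
        quota = int(round(ratio[1] * n_cls))
        uniq = sorted(set(cls_groups))
        sizes = {g: int((cls_groups == g).sum()) for g in uniq}
        base = {g: int(np.floor(ratio[1] * sizes[g])) for g in uniq}
        remainder = {g: ratio[1] * sizes[g] - base[g] for g in uniq}
        short = quota - sum(base.values())
        # largest remainder, deterministic tie-break by group name
        order = sorted(uniq, key=lambda g: (-remainder[g], g))
        take = dict(base)
        for g in order[:max(short, 0)]:
            take[g] += 1
        for g in uniq:
            members = cls_ids[cls_groups == g]
            perm = rng.permutation(len(members))
            k = min(take[g], len(members))
            test_ids.extend(members[perm[:k]])
            train_ids.extend(members[perm[k:]])

    return SplitAssignment(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                           ratio=tuple(ratio), seed=seed)
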