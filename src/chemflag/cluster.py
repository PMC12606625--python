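"""Scaffold-similarity clustering of test-set molecules.

Chain: Bemis-Murcko scaffold -> ECFP4 Tanimoto distance -> UMAP embedding
-> HDBSCAN density clustering (grid-searched, silhouette-maximised) ->
reassignment of noise points to the nearest cluster by combined MACCS +
ECFP4 similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, MACCSkeys
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import HDBSCAN
from sklearn.metrics import silhouette_score

ACYCLIC_SCAFFOLD = "__acyclic__"

DEFAULT_EMBED_GRID = {"n_neighbors": [15, 30], "min_dist": [0.0, 0.1]}
DEFAULT_CLUSTER_GRID = {"min_cluster_size": [3, 5]}


def murcko_scaffold(molecule) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold (ring systems plus
    linkers, side chains removed); :data:`ACYCLIC_SCAFFOLD` for ring-free
    molecules so no compound is ever dropped. Idempotent."""
    mol = molecule if isinstance(molecule, Chem.Mol) else Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"unparseable molecule: {molecule!r}")
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    smi = Chem.MolToSmiles(scaf) if scaf is not None else ""
    return smi if smi else ACYCLIC_SCAFFOLD


def _ecfp4_bitvect(smiles: str, n_bits: int = 1024):
    if smiles == ACYCLIC_SCAFFOLD:
        mol = Chem.MolFromSmiles("")  # empty molecule -> empty fingerprint
    else:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable scaffold: {smiles!r}")
    gen = AllChem.GetMorganGenerator(radius=2, fpSize=n_bits)
    return set(np.flatnonzero(gen.GetFingerprintAsNumPy(mol)))


def tanimoto(a: set, b: set) -> float:
    """|A n B| / |A u B|; two empty sets are defined as identical (1)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def scaffold_distance_matrix(scaffolds: list[str], n_bits: int = 1024) -> np.ndarray:
    """Symmetric 1 - Tanimoto distance on scaffold ECFP4 fingerprints."""
    if len(scaffolds) < 2:
        raise ValueError("need at least 2 scaffolds")
    fps = [_ecfp4_bitvect(s, n_bits) for s in scaffolds]
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    return d


@dataclass
class ClusterAssignment:
    molecule_ids: list[str]
    cluster_ids: np.ndarray          # int >= 0 after reassignment; -1 = noise
    noise_ids: list[str] = field(default_factory=list)
    embedding_params: dict = field(default_factory=dict)
    clustering_params: dict = field(default_factory=dict)
    silhouette: float = float("nan")
    seed: int = 0

    @property
    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.cluster_ids[self.cluster_ids >= 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        noise = set(self.noise_ids)
        return pd.DataFrame({
            "molecule_id": self.molecule_ids,
            "cluster_id": self.cluster_ids,
            "was_noise": [m in noise for m in self.molecule_ids],
        })


def embed_and_cluster(
    distances: np.ndarray,
    molecule_ids: list[str] | None = None,
    embed_grid: dict | None = None,
    cluster_grid: dict | None = None,
    seed: int = 0,
    n_components: int = 2,
) -> ClusterAssignment:
    """Grid-search UMAP x HDBSCAN, keeping the silhouette-best combination.

    The silhouette is computed in the embedded space on non-noise points.
    If no combination produces >= 2 clusters, an explicit no-structure
    result places every molecule in cluster 0.
    """
    import umap

    if embed_grid is None:
        embed_grid = DEFAULT_EMBED_GRID
    if cluster_grid is None:
        cluster_grid = DEFAULT_CLUSTER_GRID
    if not embed_grid or not cluster_grid:
        raise ValueError("parameter grids must be non-empty")
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    ids = [str(i) for i in molecule_ids] if molecule_ids is not None else [f"m{i}" for i in range(n)]

    best = None
    for nn in embed_grid.get("n_neighbors", [15]):
        for md in embed_grid.get("min_dist", [0.1]):
            nn_eff = min(nn, n - 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emb = umap.UMAP(
                    n_neighbors=nn_eff, min_dist=md, n_components=n_components,
                    metric="precomputed", random_state=seed,
                ).fit_transform(distances)
            for mcs in cluster_grid.get("min_cluster_size", [5]):
                if mcs > n:
                    continue
                labels = HDBSCAN(min_cluster_size=mcs, copy=True).fit_predict(emb)
                mask = labels >= 0
                if len(np.unique(labels[mask])) < 2 or mask.sum() < 3:
                    continue
                sil = float(silhouette_score(emb[mask], labels[mask]))
                cand = (sil, {"n_neighbors": nn_eff, "min_dist": md},
                        {"min_cluster_size": mcs}, labels)
                if best is None or sil > best[0]:
                    best = cand

    if best is None:  # no structure found under any grid point
        return ClusterAssignment(
            molecule_ids=ids, cluster_ids=np.zeros(n, dtype=int), noise_ids=[],
            embedding_params={}, clustering_params={}, silhouette=float("nan"),
            seed=seed,
        )
    sil, eparams, cparams, labels = best
    noise = [ids[i] for i in np.flatnonzero(labels < 0)]
    return ClusterAssignment(molecule_ids=ids, cluster_ids=labels.astype(int),
                             noise_ids=noise, embedding_params=eparams,
                             clustering_params=cparams, silhouette=sil, seed=seed)


def _mol_fp_sets(smiles: str, n_bits: int = 1024) -> tuple[set, set]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable molecule: {smiles!r}")
    gen = AllChem.GetMorganGenerator(radius=2, fpSize=n_bits)
    ecfp = set(np.flatnonzero(gen.GetFingerprintAsNumPy(mol)))
    maccs = set(MACCSkeys.GenMACCSKeys(mol).GetOnBits())
    return ecfp, maccs


def reassign_singletons(assignment: ClusterAssignment, smiles_by_id: dict[str, str]) -> ClusterAssignment:
    """Attach every noise molecule to the cluster maximising its mean
    combined similarity (average of MACCS and ECFP4 Tanimoto) to cluster
    members; ties break to the lower cluster id."""
    labels = assignment.cluster_ids.copy()
    noise_idx = np.flatnonzero(labels < 0)
    if len(noise_idx) == 0:
        return ClusterAssignment(list(assignment.molecule_ids), labels,
                                 list(assignment.noise_ids), dict(assignment.embedding_params),
                                 dict(assignment.clustering_params), assignment.silhouette,
                                 assignment.seed)
    clusters = sorted(set(labels[labels >= 0]))
    if not clusters:
        raise ValueError("no clusters exist to reassign singletons into")

    fps = {m: _mol_fp_sets(smiles_by_id[m]) for m in assignment.molecule_ids}
    members = {c: [assignment.molecule_ids[i] for i in np.flatnonzero(labels == c)] for c in clusters}
    for i in noise_idx:
        mid = assignment.molecule_ids[i]
        e0, m0 = fps[mid]
        best_c, best_s = None, -1.0
        for c in clusters:  # ascending ids: ties keep the lower id
            sims = [(tanimoto(e0, fps[m][0]) + tanimoto(m0, fps[m][1])) / 2.0 for m in members[c]]
            s = float(np.mean(sims))
            if s > best_s + 1e-12:
                best_c, best_s = c, s
        labels[i] = best_c
    return ClusterAssignment(list(assignment.molecule_ids), labels,
                             list(assignment.noise_ids), dict(assignment.embedding_params),
                             dict(assignment.clustering_params), assignment.silhouette,
                             assignment.seed)


def cluster_molecules(smiles: list[str], molecule_ids: list[str] | None = None,
                      seed: int = 0, embed_grid=None, cluster_grid=None) -> ClusterAssignment:
    """End-to-end scaffold clustering of a molecule list."""
    ids = [str(i) for i in molecule_ids] if molecule_ids is not None else [f"m{i}" for i in range(len(smiles))]
    scaffolds = [murcko_scaffold(s) for s in smiles]
    d = scaffold_distance_matrix(scaffolds)
    assignment = embed_and_cluster(d, ids, embed_grid, cluster_grid, seed=seed)
    return reassign_singletons(assignment, dict(zip(ids, smiles)))
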