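"""Stage-specific expression profiling, clustering and paralog-pair divergence.

Expression matrices are genes × developmental stages (FPKM-like values).
Profiles are log2(x + 1)-transformed and standardised per gene across stages
(z-scores); constant genes get all-zero z and a flag.  Genes are grouped by
k-means on the z-profiles (k = 8 by default), stage specificity is called when
exactly one stage clears a z threshold, and a paralog pair is expression-
divergent when its profiles correlate poorly or peak in different stages while
both genes are stage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class StageProfile:
    gene_id: str
    z: np.ndarray
    stages: tuple[str, ...]
    constant: bool

    @property
    def peak_stage(self) -> str:
        return self.stages[int(np.argmax(self.z))]

    @property
    def specificity(self) -> float:
        return float(np.max(self.z))


def zscore_profiles(
    matrix: pd.DataFrame,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> dict[str, StageProfile]:
    """Per-gene z-scores across stages (optional log2(x + pseudocount) first).

    The per-gene mean is 0 and the (population) standard deviation is 1, except
    for constant genes, which are all-zero and flagged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 stages")
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    x = matrix.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + pseudocount)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    z[constant, :] = 0.0
    stages = tuple(matrix.columns)
    return {
        gene: StageProfile(gene_id=gene, z=z[i], stages=stages,
                           constant=bool(constant[i]))
        for i, gene in enumerate(matrix.index)
    }


def _zmatrix(profiles: Mapping[str, StageProfile]) -> tuple[list[str], np.ndarray]:
    names = list(profiles)
    return names, np.vstack([profiles[g].z for g in names])


def cluster_stage_patterns(
    profiles: Mapping[str, StageProfile],
    k: int = 8,
    seed: int = 0,
    n_init: int = 20,
) -> dict[str, int]:
    """K-means (Euclidean, best of ``n_init`` seeded restarts) on z-profiles."""
    names, Z = _zmatrix(profiles)
    if k > len(names):
        raise ValueError(f"k={k} exceeds {len(names)} genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    return {g: int(l) for g, l in zip(names, labels)}


def stage_specificity(profile: StageProfile, z_threshold: float = 1.5) -> dict:
    """Stage-specific iff exactly one stage reaches the z threshold."""
    if profile.constant:
        return {"is_stage_specific": False, "peak_stage": None}
    above = np.nonzero(profile.z >= z_threshold)[0]
    specific = above.size == 1
    return {
        "is_stage_specific": bool(specific),
        "peak_stage": profile.peak_stage if specific else None,
    }


def pair_expression_divergence(
    profileA: StageProfile,
    profileB: StageProfile,
    r_threshold: float = 0.5,
    z_threshold: float = 1.5,
) -> dict:
    """Divergent iff the z-profiles correlate below ``r_threshold`` or both
    genes are stage-specific with different peak stages.  Constant profiles
    have no defined correlation; the call then rests on peaks alone (flagged).
    """
    if profileA.stages != profileB.stages:
        raise ValueError("profiles must share the same stage set")
    specA = stage_specificity(profileA, z_threshold)
    specB = stage_specificity(profileB, z_threshold)
    peak_divergent = (
        specA["is_stage_specific"] and specB["is_stage_specific"]
        and specA["peak_stage"] != specB["peak_stage"]
    )
    r = None
    r_undefined = profileA.constant or profileB.constant
    if not r_undefined:
        r = float(np.corrcoef(profileA.z, profileB.z)[0, 1])
    divergent = peak_divergent or (r is not None and r < r_threshold)
    return {
        "divergent": bool(divergent),
        "r": r,
        "r_undefined": r_undefined,
        "peaks": (specA["peak_stage"], specB["peak_stage"]),
        "peak_divergent": bool(peak_divergent),
    }


def paragroup_dispersion(
    assignments: Mapping[str, int],
    paragroups: Iterable[Sequence[str]],
) -> list[dict]:
    """Per paragroup: distinct expression clusters occupied by its members."""
    out = []
    for gi, grp in enumerate(paragroups):
        missing = [g for g in grp if g not in assignments]
        if missing:
            raise ValueError(f"paragroup member(s) not clustered: {missing}")
        occupied = {assignments[g] for g in grp}
        out.append({
            "paragroup": gi,
            "n_members": len(grp),
            "n_clusters_occupied": len(occupied),
            "all_same_cluster": len(occupied) == 1,
        })
    return out
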