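"""Second-level (random-effects) inference on subject-level maps.

Cluster-level family-wise error control uses group-label permutation of
the maximum cluster size — assumption-light and exactly calibrated at
small scale — rather than random-field theory. The cluster-forming
threshold and the 0.05 family-wise alpha remain ordinary parameters.
Cluster connectivity is 18-neighbour in 3-D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from dyadscan.core import DyadscanError

__all__ = [
    "two_sample_t_map",
    "one_sample_t_map",
    "label_clusters",
    "permutation_cluster_fwe",
    "factorial_effects",
    "ClusterResult",
]

#: 3-D connectivity used for cluster formation: faces + edges (18 neighbours).
CLUSTER_CONNECTIVITY = ndimage.generate_binary_structure(3, 2)


def _stack(images) -> np.ndarray:
    arr = np.asarray(images, dtype=float)
    if arr.ndim < 2:
        raise DyadscanError("expected a stack of images (n, ...)")
    return arr


def two_sample_t_map(images_a, images_b, equal_var: bool = True):
    """Voxelwise two-sample t map (pooled variance by default).

    Returns (t, df, valid); voxels where both groups have zero variance
    get t = 0 and valid = False.
    """
    a = _stack(images_a)
    b = _stack(images_b)
    if a.shape[1:] != b.shape[1:]:
        raise DyadscanError("group images must share a grid")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise DyadscanError("need at least 2 images per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df_w = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = np.where(se2 > 0, df_w, 1.0)
    valid = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, (ma - mb) / np.sqrt(np.where(valid, se2, 1.0)), 0.0)
    return t, df, valid


def one_sample_t_map(images):
    """Voxelwise one-sample t map against 0; zero-variance voxels -> 0."""
    a = _stack(images)
    n = a.shape[0]
    if n < 2:
        raise DyadscanError("need at least 2 images")
    m = a.mean(axis=0)
    v = a.var(axis=0, ddof=1)
    valid = v > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, m / np.sqrt(np.where(valid, v, 1.0) / n), 0.0)
    return t, n - 1, valid


def label_clusters(stat_map: np.ndarray, threshold: float, two_sided: bool = True):
    """Label suprathreshold clusters under 18-connectivity.

    Returns (labels array, list of cluster sizes). With ``two_sided`` the
    threshold applies to |stat|; positive and negative excursions are
    labelled separately so a cluster never straddles sign.
    """
    stat = np.asarray(stat_map, dtype=float)
    if stat.ndim != 3:
        raise DyadscanError("cluster labelling expects a 3-D map")
    labels = np.zeros(stat.shape, dtype=int)
    sizes: list[int] = []
    excursions = [stat > threshold]
    if two_sided:
        excursions.append(stat < -threshold)
    next_label = 0
    for exc in excursions:
        lab, n = ndimage.label(exc, structure=CLUSTER_CONNECTIVITY)
        for i in range(1, n + 1):
            next_label += 1
            sel = lab == i
            labels[sel] = next_label
            sizes.append(int(sel.sum()))
    return labels, sizes


@dataclass
class ClusterResult:
    """Clusters of a thresholded statistic map with permutation FWE p."""

    stat_map: np.ndarray
    threshold: float
    clusters: pd.DataFrame  # size, peak_stat, peak_ijk, p_fwe
    labels: np.ndarray
    null_max_sizes: np.ndarray
    n_perm: int

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Union of clusters with FWE p below alpha."""
        mask = np.zeros(self.stat_map.shape, dtype=bool)
        for _, row in self.clusters.iterrows():
            if row["p_fwe"] < alpha:
                mask |= self.labels == row["label"]
        return mask


def _cluster_table(stat, labels, sizes, null_max, n_perm):
    rows = []
    for i, size in enumerate(sizes, start=1):
        sel = labels == i
        vals = stat[sel]
        peak_flat = np.abs(vals).argmax()
        peak_idx = tuple(int(c[peak_flat]) for c in np.nonzero(sel))
        p = (1 + int(np.sum(null_max >= size))) / (n_perm + 1)
        rows.append(
            {
                "label": i,
                "size": size,
                "peak_stat": float(vals[peak_flat]),
                "peak_ijk": peak_idx,
                "p_fwe": float(p),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "size", "peak_stat", "peak_ijk", "p_fwe"]
    )


def permutation_cluster_fwe(
    images_a,
    images_b,
    threshold: float,
    n_perm: int = 1000,
    two_sided: bool = True,
    equal_var: bool = True,
    seed=None,
) -> ClusterResult:
    """Two-sample cluster inference with label-permutation FWE control.

    The observed t map is thresholded and its clusters compared against
    the permutation distribution of the maximum cluster size obtained by
    shuffling group membership: p_FWE = (1 + #{max cluster >= observed
    size}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p values are coarse")
    a = _stack(images_a)
    b = _stack(images_b)
    if a.ndim != 4:
        raise DyadscanError("cluster inference expects stacks of 3-D images")
    t_obs, _, _ = two_sample_t_map(a, b, equal_var=equal_var)
    labels, sizes = label_clusters(t_obs, threshold, two_sided=two_sided)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    n_tot = pooled.shape[0]
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n_tot)
        t_p, _, _ = two_sample_t_map(
            pooled[perm[:na]], pooled[perm[na:]], equal_var=equal_var
        )
        _, perm_sizes = label_clusters(t_p, threshold, two_sided=two_sided)
        null_max[p] = max(perm_sizes, default=0)

    clusters = _cluster_table(t_obs, labels, sizes, null_max, n_perm)
    return ClusterResult(
        stat_map=t_obs,
        threshold=threshold,
        clusters=clusters,
        labels=labels,
        null_max_sizes=null_max,
        n_perm=n_perm,
    )


# Within-cell ordering for the 2 (cue) x 2 (attention) layout.
_CELLS = (("eye", "shared"), ("eye", "nonshared"), ("ball", "shared"), ("ball", "nonshared"))
_CUE_W = np.array([0.5, 0.5, -0.5, -0.5])
_ATT_W = np.array([0.5, -0.5, 0.5, -0.5])
_INT_W = np.array([1.0, -1.0, -1.0, 1.0])


def factorial_effects(images: dict) -> dict:
    """t maps for a 2 (group) x 2 (cue) x 2 (attention) mixed design.

    ``images`` maps the two group names to per-group dicts keyed by
    (cue, attention) cells — ("eye"|"ball", "shared"|"nonshared") — each
    an (n_subjects, ...) stack with consistent subject ordering across
    cells. Group is between subjects; cue and attention are within.
    Each effect is a contrast over cell means, carried per subject and
    tested with a one-sample (within effects) or two-sample (anything
    involving group) t map. Returns {effect: (t, df, valid)}.
    """
    if len(images) != 2:
        raise DyadscanError("factorial design needs exactly two groups")
    (g1, cells1), (g2, cells2) = images.items()
    per_group = []
    for gname, cells in ((g1, cells1), (g2, cells2)):
        missing = [c for c in _CELLS if c not in cells]
        if missing:
            raise DyadscanError(f"group {gname!r} is missing cells: {missing}")
        stacks = [_stack(cells[c]) for c in _CELLS]
        ns = {s.shape[0] for s in stacks}
        if len(ns) != 1:
            raise DyadscanError(
                f"group {gname!r}: every subject must contribute one image per cell"
            )
        per_group.append(np.stack(stacks, axis=1))  # (n, 4, ...)
    s1, s2 = per_group

    def within(stack, w):
        return np.tensordot(stack, w, axes=([1], [0]))

    def mean_cells(stack):
        return stack.mean(axis=1)

    out = {
        "group": two_sample_t_map(mean_cells(s1), mean_cells(s2)),
        "cue": one_sample_t_map(
            np.concatenate([within(s1, _CUE_W), within(s2, _CUE_W)], axis=0)
        ),
        "attention": one_sample_t_map(
            np.concatenate([within(s1, _ATT_W), within(s2, _ATT_W)], axis=0)
        ),
        "cue_x_attention": one_sample_t_map(
            np.concatenate([within(s1, _INT_W), within(s2, _INT_W)], axis=0)
        ),
        "group_x_cue": two_sample_t_map(within(s1, _CUE_W), within(s2, _CUE_W)),
        "group_x_attention": two_sample_t_map(within(s1, _ATT_W), within(s2, _ATT_W)),
        "group_x_cue_x_attention": two_sample_t_map(
            within(s1, _INT_W), within(s2, _INT_W)
        ),
    }
    return out
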