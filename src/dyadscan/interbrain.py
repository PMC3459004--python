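"""Inter-brain coherence: residual correlation across partners with the
pseudo-pair null.

Two participants scanned simultaneously may share signal that no task
regressor explains. After removing the task model, the residual series of
subject A and subject B are correlated voxel by voxel (same grid position
in both normalised brains) and Fisher z-transformed. The empirical null is
built by recombining subjects across sessions: of all nA x nB
combinations, the few that were actually scanned together are "Pairs" and
the rest "Non-pairs". A genuinely pair-specific signal elevates Pair z
over Non-pair z; anything driven by the common task structure alone
inflates both equally. The two experiments (e.g. ASD-Normal vs
Normal-Normal dyads) are then crossed with Pairing in a two-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from dyadscan.core import DyadscanError, flatten_spatial

__all__ = [
    "enumerate_pairings",
    "fisher_z",
    "interbrain_correlation_map",
    "roi_mean_series",
    "pairing_anova",
    "pairing_permutation_test",
    "CoherenceMap",
    "PairingAnovaResult",
]

#: Correlations are clipped to 1 - 1e-6 in magnitude before artanh so that
#: identical series yield a finite (if extreme) z.
R_CLIP = 1.0 - 1e-6


def enumerate_pairings(
    subjects_a,
    subjects_b,
    true_pairs: dict | None = None,
    experiment: str = "",
) -> pd.DataFrame:
    """All A x B subject combinations, flagged true pair or pseudo-pair.

    Parameters
    ----------
    subjects_a, subjects_b:
        Subject identifiers (or integers, expanded to ``A00..``/``B00..``).
    true_pairs:
        Bijection {subject_a: subject_b} marking who was scanned with
        whom. Defaults to positional pairing of the first min(nA, nB)
        subjects.

    Returns a DataFrame with columns subject_a, subject_b, is_true_pair,
    experiment, in deterministic row-major order.
    """
    if isinstance(subjects_a, (int, np.integer)):
        subjects_a = [f"A{i:02d}" for i in range(subjects_a)]
    if isinstance(subjects_b, (int, np.integer)):
        subjects_b = [f"B{i:02d}" for i in range(subjects_b)]
    subjects_a = list(subjects_a)
    subjects_b = list(subjects_b)
    if len(set(subjects_a)) != len(subjects_a) or len(set(subjects_b)) != len(
        subjects_b
    ):
        raise DyadscanError("duplicate subject ids")
    if not subjects_a or not subjects_b:
        raise DyadscanError("need at least one subject per side")
    if true_pairs is None:
        k = min(len(subjects_a), len(subjects_b))
        true_pairs = dict(zip(subjects_a[:k], subjects_b[:k]))
    if len(set(true_pairs.values())) != len(true_pairs):
        raise DyadscanError("true_pairs must be a bijection")
    unknown = (set(true_pairs) - set(subjects_a)) | (
        set(true_pairs.values()) - set(subjects_b)
    )
    if unknown:
        raise DyadscanError(f"true_pairs references unknown subjects: {sorted(unknown)}")
    rows = [
        (sa, sb, true_pairs.get(sa) == sb, experiment)
        for sa in subjects_a
        for sb in subjects_b
    ]
    return pd.DataFrame(
        rows, columns=["subject_a", "subject_b", "is_true_pair", "experiment"]
    )


def fisher_z(r):
    """Fisher r-to-z (artanh), with |r| clipped just below 1.

    Odd and monotone; |r| > 1 is rejected.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise DyadscanError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(z) if np.isscalar(r) else z


@dataclass
class CoherenceMap:
    """Per-voxel Fisher-z inter-brain correlation for one pairing."""

    z: np.ndarray
    valid: np.ndarray  # False where either subject's voxel had no variance
    subject_a: str = ""
    subject_b: str = ""
    spatial_shape: tuple[int, int, int] | None = None

    def z_map(self) -> np.ndarray:
        if self.spatial_shape is not None:
            return self.z.reshape(self.spatial_shape)
        return self.z


def _standardise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    x = np.where(ok, x / np.where(ok, sd, 1.0), 0.0)
    return x, ok


def interbrain_correlation_map(
    residuals_a,
    residuals_b,
    subject_a: str = "",
    subject_b: str = "",
) -> CoherenceMap:
    """Voxelwise Pearson correlation of two subjects' residual series at
    identical grid positions, Fisher z-transformed.

    Inputs are (T, V) or (X, Y, Z, T) with matching geometry. Voxels with
    zero variance in either subject get z = 0 and valid = False.
    Symmetric in its two arguments.
    """
    arr_a = np.asarray(residuals_a, dtype=float)
    spatial_shape = arr_a.shape[:3] if arr_a.ndim == 4 else None
    a = flatten_spatial(arr_a)
    b = flatten_spatial(np.asarray(residuals_b, dtype=float))
    if a.shape != b.shape:
        raise DyadscanError(
            f"residual shapes differ: {a.shape} vs {b.shape}"
        )
    t = a.shape[0]
    if t < 3:
        raise DyadscanError("need at least 3 time points")
    a, ok_a = _standardise(a)
    b, ok_b = _standardise(b)
    r = np.einsum("tv,tv->v", a, b) / t
    valid = ok_a & ok_b
    z = np.where(valid, fisher_z(np.clip(r, -1.0, 1.0)), 0.0)
    return CoherenceMap(
        z=z,
        valid=valid,
        subject_a=subject_a,
        subject_b=subject_b,
        spatial_shape=spatial_shape,
    )


def roi_mean_series(residuals, mask) -> np.ndarray:
    """Unweighted mean residual time course over the mask voxels."""
    x = flatten_spatial(np.asarray(residuals, dtype=float))
    m = np.asarray(mask).reshape(-1).astype(bool)
    if m.shape[0] != x.shape[1]:
        raise DyadscanError("mask size does not match voxel count")
    if not m.any():
        raise DyadscanError("empty ROI mask")
    return x[:, m].mean(axis=1)


@dataclass
class PairingAnovaResult:
    """Two-way Experiment x Pairing ANOVA on pairing-level z values."""

    anova: pd.DataFrame  # statsmodels anova_lm table (type II)
    cell_means: pd.DataFrame
    posthoc: pd.DataFrame

    @property
    def interaction_F(self) -> float:
        return float(self.anova.loc["C(experiment):C(pairing)", "F"])

    @property
    def interaction_p(self) -> float:
        return float(self.anova.loc["C(experiment):C(pairing)", "PR(>F)"])

    @property
    def df_denominator(self) -> int:
        return int(self.anova.loc["Residual", "df"])


def pairing_anova(data: pd.DataFrame, z_col: str = "z") -> PairingAnovaResult:
    """Fixed-effects Experiment x Pairing ANOVA with interaction.

    ``data`` needs columns ``experiment``, ``is_true_pair`` (or a
    ``pairing`` column with labels) and the z values. Every combination is
    treated as one independent observation — the convention of the
    original analysis; see :func:`pairing_permutation_test` for a
    dependence-aware alternative. Post hocs are Bonferroni-corrected
    Pair vs Non-pair t tests within each experiment.
    """
    df = data.copy()
    if "pairing" not in df.columns:
        if "is_true_pair" not in df.columns:
            raise DyadscanError("need a pairing or is_true_pair column")
        df["pairing"] = np.where(df["is_true_pair"], "Pair", "Non-pair")
    cells = df.groupby(["experiment", "pairing"])[z_col].agg(["mean", "size", "sem"])
    if len(cells) != 4:
        raise DyadscanError("need observations in all four Experiment x Pairing cells")
    df = df.rename(columns={z_col: "_z"})
    model = smf.ols("_z ~ C(experiment) * C(pairing)", data=df).fit()
    table = anova_lm(model, typ=2)

    rows = []
    n_comparisons = df["experiment"].nunique()
    for exp, grp in df.groupby("experiment"):
        pair = grp.loc[grp["pairing"] == "Pair", "_z"]
        non = grp.loc[grp["pairing"] == "Non-pair", "_z"]
        t, p = stats.ttest_ind(pair, non)
        rows.append(
            {
                "experiment": exp,
                "comparison": "Pair vs Non-pair",
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, n_comparisons * p)),
            }
        )
    return PairingAnovaResult(
        anova=table, cell_means=cells, posthoc=pd.DataFrame(rows)
    )


def pairing_permutation_test(
    z_matrix: np.ndarray,
    n_perm: int = 2000,
    seed=None,
) -> dict:
    """Subject-level permutation companion to the pairing contrast.

    Not part of the original analysis: the ANOVA above treats all
    combinations as independent although pseudo-pairs reuse subjects.
    Here the observed statistic is mean(diagonal) - mean(off-diagonal) of
    the nA x nB z matrix, and the null relabels which B subject belongs to
    which A subject (random permutations of the B side), which preserves
    the dependence structure exactly.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise DyadscanError("z_matrix must be square (true pairs on the diagonal)")
    n = z.shape[0]
    diag = np.eye(n, dtype=bool)
    obs = z[diag].mean() - z[~diag].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d = z[np.arange(n), perm].mean()
        stat = d - (z.sum() - z[np.arange(n), perm].sum()) / (n * n - n)
        if stat >= obs:
            count += 1
    return {
        "observed": float(obs),
        "p": float((1 + count) / (n_perm + 1)),
        "n_perm": n_perm,
    }
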