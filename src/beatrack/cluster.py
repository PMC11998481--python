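"""Permutation nulls and group-level inference over electrodes.

The surrogate construction cuts the continuous stimulus feature into 1-s
segments and permutes them: local signal statistics survive, the temporal
relation to the recording does not. MI recomputed against many such
surrogates gives a per-channel null distribution; group-level tests then
form spatially adjacent supra-threshold electrode clusters (minimum two
electrodes) and compare each cluster's summed statistic to the null
distribution of per-permutation maximal cluster statistics, which controls
the family-wise error rate at the cluster level.

Three cluster tests are provided: MI against chance (one-sided, group-mean
MI as the channel statistic), paired condition contrasts (two-tailed paired
t with a critical value from the Student-t distribution), and correlations
between MI and per-participant behavioral measures (Fisher-z transformed
Pearson or Spearman r). Hemispheric lateralization uses paired t-tests with
Benjamini-Hochberg FDR, and the regression models are ordinary least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from ._seeds import child_rng
from .features import FilterSpec
from .montage import Montage
from .recording import Recording
from .signals import ContinuousSignal
from .tracking import MIMap, _copula_rows, bandpass, block_mi_bits

__all__ = [
    "Adjacency",
    "ClusterResult",
    "CorrelationMap",
    "RegressionResult",
    "segment_shuffle",
    "permutation_null",
    "track_with_null",
    "cluster_vs_chance",
    "cluster_condition_contrast",
    "cluster_correlation",
    "lateralization_test",
    "linear_model",
    "with_interaction",
    "fisher_z",
    "t_critical",
    "cohens_d_from_t",
]

MAX_FISHER_Z = float(np.arctanh(1.0 - 1e-15))


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

@dataclass
class Adjacency:
    """Symmetric neighbor sets per channel label."""

    neighbors: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.neighbors = {k: frozenset(v) for k, v in self.neighbors.items()}
        for ch, nbrs in self.neighbors.items():
            if ch in nbrs:
                raise ValueError(f"channel {ch!r} is its own neighbor")
            for other in nbrs:
                if ch not in self.neighbors.get(other, frozenset()):
                    raise ValueError(f"adjacency not symmetric: {ch!r} -> {other!r}")

    @classmethod
    def from_montage(
        cls, montage: Montage, labels: list[str] | None = None, threshold: float = 0.6
    ) -> "Adjacency":
        """Neighbors = channel pairs within ``threshold`` of the (normalized)
        head radius on the montage."""
        labels = labels if labels is not None else montage.labels
        pos = montage.array(labels)
        radius = np.linalg.norm(pos, axis=1).max()
        pos = pos / radius
        dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        nbrs = {
            labels[i]: frozenset(
                labels[j] for j in range(len(labels)) if j != i and dist[i, j] < threshold
            )
            for i in range(len(labels))
        }
        return cls(neighbors=nbrs)

    def index_lists(self, labels: list[str]) -> list[np.ndarray]:
        missing = [l for l in labels if l not in self.neighbors]
        if missing:
            raise ValueError(f"adjacency is missing channels: {missing}")
        pos = {l: i for i, l in enumerate(labels)}
        return [
            np.array(sorted(pos[o] for o in self.neighbors[l] if o in pos), dtype=int)
            for l in labels
        ]


def _components(mask: np.ndarray, nbr_idx: list[np.ndarray], min_size: int) -> list[np.ndarray]:
    """Connected components of True channels, keeping those >= min_size."""
    seen = np.zeros(mask.size, dtype=bool)
    out = []
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in nbr_idx[node]:
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        if len(comp) >= min_size:
            out.append(np.array(sorted(comp), dtype=int))
    return out


def _max_cluster_stat(
    values: np.ndarray, mask: np.ndarray, nbr_idx: list[np.ndarray], min_size: int
) -> float:
    comps = _components(mask, nbr_idx, min_size)
    if not comps:
        return 0.0
    return max(abs(float(values[c].sum())) for c in comps)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters with summed statistic, permutation p-values, and the null."""

    clusters: list[dict]
    null_distribution: np.ndarray
    n_perm: int
    alpha: float = 0.05

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p_value"] <= self.alpha]

    def to_records(self) -> list[dict]:
        return [
            {
                "channels": list(c["channels"]),
                "stat": c["cluster_stat"],
                "p": c["p_value"],
                "sign": c["sign"],
                "mi_sum": c.get("mi_sum"),
            }
            for c in self.clusters
        ]


@dataclass
class CorrelationMap:
    """Per-channel correlation between MI and a behavioral measure."""

    r: np.ndarray
    fisher_z: np.ndarray
    labels: list[str]
    behavioral: str = ""


@dataclass
class RegressionResult:
    """OLS fit summary: per-term coefficients/t/p, overall F, df, R^2."""

    terms: list[str]
    coefficients: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    f_value: float
    df: tuple[int, int]
    r_squared: float


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

def segment_shuffle(
    signal: ContinuousSignal, seg_len: float = 1.0, seed: int = 0
) -> ContinuousSignal:
    """Permute whole ``seg_len`` segments of the signal.

    The trailing partial segment stays in place, so the sample multiset is
    preserved exactly and no resampling is needed.
    """
    if seg_len <= 0:
        raise ValueError("seg_len must be > 0")
    nseg = int(round(seg_len * signal.fs))
    n_full = len(signal) // nseg
    if n_full < 2:
        raise ValueError("signal must cover at least two full segments")
    rng = child_rng(seed, "segment_shuffle")
    order = rng.permutation(n_full)
    head = signal.samples[: n_full * nseg].reshape(n_full, nseg)[order].ravel()
    return signal.copy_with(np.concatenate([head, signal.samples[n_full * nseg :]]))


def _shuffled_stack(
    samples: np.ndarray, nseg: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) stack of segment-shuffled copies of a 1-D signal."""
    n = samples.size
    n_full = n // nseg
    head = samples[: n_full * nseg].reshape(n_full, nseg)
    out = np.empty((n_perm, n))
    for p in range(n_perm):
        out[p, : n_full * nseg] = head[rng.permutation(n_full)].ravel()
    out[:, n_full * nseg :] = samples[n_full * nseg :]
    return out


def permutation_null(
    rec: Recording,
    features: list[ContinuousSignal] | ContinuousSignal,
    band: FilterSpec = FilterSpec(0.5, 3.0),
    lag: float = 100.0,
    n_perm: int = 3000,
    seed: int = 0,
    *,
    seg_len: float = 1.0,
    discard: float = 0.5,
    bias_correct: bool = True,
) -> np.ndarray:
    """(channels, n_perm) MI null from segment-shuffled features.

    Each permutation runs through the identical pipeline as the observed
    statistic: shuffle the raw feature(s), band-pass, advance the recording
    by the lag, discard the initial transient, copula-normalize, MI.
    """
    feats = features if isinstance(features, list) else [features]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fs = rec.fs
    for f in feats:
        if f.fs != fs:
            raise ValueError("features must share the recording sampling rate")
    n = min(rec.n_samples, min(len(f) for f in feats))
    nseg = int(round(seg_len * fs))
    lag_samples = int(round(lag / 1000.0 * fs))
    skip = int(round(discard * fs))
    if lag_samples + skip >= n:
        raise ValueError("lag plus discard exceeds the signal length")
    rng = child_rng(seed, "permutation_null")

    data = bandpass(rec.data[:, :n], fs, band)[:, lag_samples:][:, skip:]
    zch = _copula_rows(data)

    k = len(feats)
    stacks = np.empty((n_perm, k, n))
    for j, f in enumerate(feats):
        stacks[:, j, :] = _shuffled_stack(f.samples[:n], nseg, n_perm, rng)
    filt = bandpass(stacks.reshape(n_perm * k, n), fs, band)
    filt = filt[:, : n - lag_samples][:, skip:]
    zft = _copula_rows(filt).reshape(n_perm, k, -1)
    return block_mi_bits(zch, zft, bias_correct=bias_correct)


def track_with_null(
    rec: Recording,
    features,
    band: FilterSpec,
    lag: float,
    n_perm: int,
    seed: int,
    *,
    seg_len: float = 1.0,
    discard: float = 0.5,
    bias_correct: bool = True,
    feature_name: str = "envelope",
    participant: str = "",
    condition: str = "",
) -> tuple[MIMap, np.ndarray]:
    """Observed MI map and its segment-shuffle null in one pass.

    Identical to :func:`beatrack.tracking.track` followed by
    :func:`permutation_null`, but the recording is filtered and normalized
    once (the observed feature rides along as permutation index 0 internally).
    """
    feats = features if isinstance(features, list) else [features]
    fs = rec.fs
    for f in feats:
        if f.fs != fs:
            raise ValueError("features must share the recording sampling rate")
    n = min(rec.n_samples, min(len(f) for f in feats))
    nseg = int(round(seg_len * fs))
    lag_samples = int(round(lag / 1000.0 * fs))
    skip = int(round(discard * fs))
    if lag_samples + skip >= n:
        raise ValueError("lag plus discard exceeds the signal length")
    rng = child_rng(seed, "permutation_null")

    data = bandpass(rec.data[:, :n], fs, band)[:, lag_samples:][:, skip:]
    zch = _copula_rows(data)

    k = len(feats)
    stacks = np.empty((n_perm + 1, k, n))
    for j, f in enumerate(feats):
        stacks[0, j, :] = f.samples[:n]
        stacks[1:, j, :] = _shuffled_stack(f.samples[:n], nseg, n_perm, rng)
    filt = bandpass(stacks.reshape((n_perm + 1) * k, n), fs, band)
    filt = filt[:, : n - lag_samples][:, skip:]
    zft = _copula_rows(filt).reshape(n_perm + 1, k, -1)
    mi_all = block_mi_bits(zch, zft, bias_correct=bias_correct)
    mimap = MIMap(
        mi=mi_all[:, 0],
        labels=list(rec.labels),
        feature=feature_name,
        band=(band.low, band.high),
        lag=float(lag),
        participant=participant,
        condition=condition,
    )
    return mimap, mi_all[:, 1:]


# ---------------------------------------------------------------------------
# Cluster tests
# ---------------------------------------------------------------------------

def _perm_p(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def cluster_vs_chance(
    group_mi: np.ndarray,
    group_nulls: np.ndarray,
    labels: list[str],
    adjacency: Adjacency,
    min_size: int = 2,
    alpha: float = 0.05,
) -> ClusterResult:
    """Group-mean MI against the segment-shuffle chance level.

    ``group_mi``: (participants, channels). ``group_nulls``: (participants,
    channels, n_perm) with matched surrogate indices across participants.
    Channels whose group mean exceeds the per-channel 95th percentile of the
    null group mean form candidate clusters (adjacency, minimum size);
    cluster statistic = summed group-mean MI, compared one-sided to the null
    of per-permutation maximal cluster statistics.
    """
    group_mi = np.asarray(group_mi, dtype=float)
    group_nulls = np.asarray(group_nulls, dtype=float)
    if group_mi.shape[1] != len(labels) or group_nulls.shape[:2] != group_mi.shape:
        raise ValueError("shape mismatch between MI, nulls and labels")
    nbr_idx = adjacency.index_lists(labels)
    n_perm = group_nulls.shape[2]

    mean_mi = group_mi.mean(axis=0)  # (C,)
    null_mean = group_nulls.mean(axis=0)  # (C, n_perm)
    # thresholds over the combined reference set (nulls + observed): every
    # member, observed included, is judged against bounds containing itself,
    # which keeps the randomization test exchangeable and its level exact
    thresh = np.percentile(np.column_stack([null_mean, mean_mi]), 95, axis=1)

    comps = _components(mean_mi > thresh, nbr_idx, min_size)
    null_max = np.array(
        [
            _max_cluster_stat(null_mean[:, p], null_mean[:, p] > thresh, nbr_idx, min_size)
            for p in range(n_perm)
        ]
    )
    clusters = []
    for comp in comps:
        stat = float(mean_mi[comp].sum())
        clusters.append(
            {
                "channels": [labels[i] for i in comp],
                "cluster_stat": stat,
                "p_value": _perm_p(null_max, stat),
                "sign": 1,
                "mi_sum": stat,
            }
        )
    return ClusterResult(clusters=clusters, null_distribution=null_max, n_perm=n_perm, alpha=alpha)


def _paired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column paired t statistic (zero-variance differences give t=0)."""
    d = a - b
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    mean = d.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def t_critical(n: int, alpha: float = 0.05) -> float:
    """Two-tailed Student-t critical value for a paired test on n subjects."""
    return float(sstats.t.ppf(1 - alpha / 2, n - 1))


def cohens_d_from_t(t: float, n: int) -> float:
    """Effect size of a paired t statistic: d = t / sqrt(n)."""
    return float(t / np.sqrt(n))


def cluster_condition_contrast(
    mi_a: np.ndarray,
    mi_b: np.ndarray,
    nulls_a: np.ndarray,
    nulls_b: np.ndarray,
    labels: list[str],
    adjacency: Adjacency,
    t_crit: float | None = None,
    min_size: int = 2,
    alpha: float = 0.05,
) -> ClusterResult:
    """Paired condition contrast of MI with a cluster permutation null.

    Channels with |t| above ``t_crit`` (default: the two-tailed 5% Student-t
    critical value for the number of participants) are clustered by sign;
    the null pairs each permutation's surrogate MI across conditions and
    applies the identical thresholding, collecting maximal |cluster t-sum|.
    """
    mi_a, mi_b = np.asarray(mi_a, float), np.asarray(mi_b, float)
    if mi_a.shape != mi_b.shape:
        raise ValueError("conditions must have matching participant x channel shapes")
    n_part = mi_a.shape[0]
    if t_crit is None:
        t_crit = t_critical(n_part)
    nbr_idx = adjacency.index_lists(labels)
    n_perm = nulls_a.shape[2]

    t_obs = _paired_t(mi_a, mi_b)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        t_null = _paired_t(nulls_a[:, :, p], nulls_b[:, :, p])
        null_max[p] = _max_cluster_stat(t_null, np.abs(t_null) > t_crit, nbr_idx, min_size)

    clusters = []
    for sign in (1, -1):
        mask = (sign * t_obs) > t_crit
        for comp in _components(mask, nbr_idx, min_size):
            stat = float(t_obs[comp].sum())
            clusters.append(
                {
                    "channels": [labels[i] for i in comp],
                    "cluster_stat": stat,
                    "p_value": _perm_p(null_max, abs(stat)),
                    "sign": sign,
                }
            )
    return ClusterResult(clusters=clusters, null_distribution=null_max, n_perm=n_perm, alpha=alpha)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh(r), guarded to the largest representable value at |r| = 1."""
    return np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))


def _corr_cols(behavior: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Pearson r between one vector and each column (vectorized)."""
    b = behavior - behavior.mean()
    v = values - values.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(b) * np.linalg.norm(v, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, b @ v / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def cluster_correlation(
    group_mi: np.ndarray,
    behavioral: np.ndarray,
    group_nulls: np.ndarray,
    labels: list[str],
    adjacency: Adjacency,
    min_size: int = 2,
    alpha: float = 0.05,
    *,
    behavioral_name: str = "",
    method: str = "pearson",
) -> tuple[ClusterResult, CorrelationMap]:
    """Brain-behavior correlation clusters against the permutation null.

    Per channel the (Fisher-z transformed) correlation between participants'
    MI and the behavioral measure is compared to the same correlation
    computed with each permutation's surrogate MI; channels outside the
    two-sided 2.5/97.5 percentile bounds are clustered by sign.
    ``method="spearman"`` runs the rank-based sensitivity variant.
    """
    group_mi = np.asarray(group_mi, float)
    behavioral = np.asarray(behavioral, float)
    n_part = group_mi.shape[0]
    if n_part < 5:
        raise ValueError("need at least 5 participants")
    if np.ptp(behavioral) == 0:
        raise ValueError("behavioral vector is constant")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    nbr_idx = adjacency.index_lists(labels)
    n_perm = group_nulls.shape[2]

    if method == "spearman":
        behavioral = sstats.rankdata(behavioral)
        group_mi = np.apply_along_axis(sstats.rankdata, 0, group_mi)
        group_nulls = np.apply_along_axis(sstats.rankdata, 0, group_nulls)

    r_obs = _corr_cols(behavioral, group_mi)
    z_obs = np.asarray(fisher_z(r_obs))
    z_null = np.empty((len(labels), n_perm))
    for p in range(n_perm):
        z_null[:, p] = fisher_z(_corr_cols(behavioral, group_nulls[:, :, p]))
    # combined reference set (nulls + observed), as in cluster_vs_chance:
    # symmetric self-inclusion keeps the test's level exact
    reference = np.column_stack([z_null, z_obs])
    lo = np.percentile(reference, 100 * alpha / 2, axis=1)
    hi = np.percentile(reference, 100 * (1 - alpha / 2), axis=1)

    null_max = np.array(
        [
            _max_cluster_stat(
                z_null[:, p],
                (z_null[:, p] > hi) | (z_null[:, p] < lo),
                nbr_idx,
                min_size,
            )
            for p in range(n_perm)
        ]
    )
    clusters = []
    for sign, mask in ((1, z_obs > hi), (-1, z_obs < lo)):
        for comp in _components(mask, nbr_idx, min_size):
            stat = float(z_obs[comp].sum())
            clusters.append(
                {
                    "channels": [labels[i] for i in comp],
                    "cluster_stat": stat,
                    "p_value": _perm_p(null_max, abs(stat)),
                    "sign": sign,
                }
            )
    result = ClusterResult(
        clusters=clusters, null_distribution=null_max, n_perm=n_perm, alpha=alpha
    )
    cmap = CorrelationMap(r=r_obs, fisher_z=z_obs, labels=list(labels), behavioral=behavioral_name)
    return result, cmap


# ---------------------------------------------------------------------------
# Lateralization and regression
# ---------------------------------------------------------------------------

def lateralization_test(
    values: np.ndarray,
    labels: list[str],
    tests: list,
) -> pd.DataFrame:
    """Hemispheric difference tests with BH-FDR correction.

    Each entry of ``tests`` is one test: a single ``(left, right)`` channel
    pair or a list of pairs whose left/right members are averaged per
    participant before a two-sided paired t-test. Returns a DataFrame with
    t, p and BH-corrected p (q = 0.05 scale) per test.
    """
    values = np.asarray(values, float)
    idx = {l: i for i, l in enumerate(labels)}
    rows = []
    for test in tests:
        pairs = [test] if isinstance(test[0], str) else list(test)
        for left, right in pairs:
            for ch in (left, right):
                if ch not in idx:
                    raise ValueError(f"unmatched channel label: {ch!r}")
        left_mean = values[:, [idx[l] for l, _ in pairs]].mean(axis=1)
        right_mean = values[:, [idx[r] for _, r in pairs]].mean(axis=1)
        diff = left_mean - right_mean
        if np.ptp(diff) == 0 and diff.mean() == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sstats.ttest_rel(left_mean, right_mean)
        rows.append({"pairs": pairs, "t": float(t), "p": float(p)})
    pvals = np.array([r["p"] for r in rows])
    reject, p_fdr = sm.stats.multipletests(pvals, alpha=0.05, method="fdr_bh")[:2]
    for r, pf, rej in zip(rows, p_fdr, reject):
        r["p_fdr"] = float(pf)
        r["reject"] = bool(rej)
    return pd.DataFrame(rows)


def with_interaction(design: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Append an ``a x b`` product column to a design frame."""
    out = design.copy()
    out[f"{a} x {b}"] = design[a] * design[b]
    return out


def linear_model(outcome: np.ndarray, design: pd.DataFrame) -> RegressionResult:
    """OLS of the outcome on named predictor columns (intercept added)."""
    y = np.asarray(outcome, float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        terms=list(X.columns),
        coefficients=np.asarray(fit.params),
        t_values=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        f_value=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        r_squared=float(fit.rsquared),
    )
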