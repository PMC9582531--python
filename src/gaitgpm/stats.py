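"""Within-subject 2x2 inference and cluster-based permutation tests.

Main effects compare each subject's factor-level means; the interaction
submits the paired differences of the task contrast per terrain level
(a difference of differences).  Cluster tests threshold the bin-wise paired
t-map, form clusters under 4-connectivity in the frequency x phase plane,
score them by the sum of t (cluster mass), and compare against the maximal
cluster mass under random per-subject sign flips.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

EFFECTS = ("terrain", "task", "interaction")
CONDITION_ORDER = ("even_ST", "even_DT", "uneven_ST", "uneven_DT")


@dataclass
class ConditionMaps:
    """Per-subject GPM maps for the four conditions at one channel.

    maps[condition] has shape (n_subjects, n_freq, n_phase); all conditions
    share the grid and subject order.
    """

    maps: dict[str, np.ndarray]
    freqs_hz: np.ndarray
    n_subjects: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CONDITION_ORDER if c not in self.maps]
        if missing:
            raise ValueError(f"missing conditions: {missing}")
        shapes = {self.maps[c].shape for c in CONDITION_ORDER}
        if len(shapes) != 1:
            raise ValueError("condition maps must share shape")
        self.n_subjects = self.maps[CONDITION_ORDER[0]].shape[0]


@dataclass
class StatsParams:
    n_permutations: int = 1000
    cluster_alpha: float = 0.05  # two-tailed cluster-forming threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float
    p_value: float
    cohens_d: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    null_max_mass: np.ndarray
    params: StatsParams

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


class EffectKind(str, enum.Enum):
    COHENS_DZ = "cohens_dz"
    PARTIAL_ETA_SQUARED = "partial_eta_squared"
    RANK_R = "rank_R"


@dataclass
class EffectSize:
    kind: EffectKind
    value: float
    n: int
    degenerate: bool = False  # zero-SD guard tripped


def effect_maps(maps: ConditionMaps, effect: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject paired maps (a, b) for the requested 2x2 effect."""
    m = maps.maps
    if effect == "terrain":
        a = 0.5 * (m["even_ST"] + m["even_DT"])
        b = 0.5 * (m["uneven_ST"] + m["uneven_DT"])
    elif effect == "task":
        a = 0.5 * (m["even_ST"] + m["uneven_ST"])
        b = 0.5 * (m["even_DT"] + m["uneven_DT"])
    elif effect == "interaction":
        # half-scaled task contrast per terrain level: a pure +-c interaction
        # pattern then yields a paired difference of 2c, on the same scale as
        # the main-effect contrasts (the paired t is scale-invariant anyway)
        a = 0.5 * (m["even_ST"] - m["even_DT"])
        b = 0.5 * (m["uneven_ST"] - m["uneven_DT"])
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return a, b


def _paired_t_map(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return mean / (sd / np.sqrt(n))


def _clusters_and_masses(t_map: np.ndarray, thresh: float
                         ) -> tuple[list[np.ndarray], list[float]]:
    masks, masses = [], []
    structure = ndimage.generate_binary_structure(t_map.ndim, 1)  # 4-connectivity
    for sign in (1, -1):
        lab, n_lab = ndimage.label(sign * t_map > thresh, structure=structure)
        for k in range(1, n_lab + 1):
            mask = lab == k
            masks.append(mask)
            masses.append(float(t_map[mask].sum()))
    return masks, masses


def _max_null_mass(diffs: np.ndarray, thresh: float, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Max |cluster mass| under per-subject sign flips, vectorized t-maps."""
    n = diffs.shape[0]
    flat = diffs.reshape(n, -1)
    sq_sum = (flat ** 2).sum(axis=0)  # invariant under sign flips
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ flat / n
    var = (sq_sum[np.newaxis, :] - n * means ** 2) / (n - 1)
    var[var <= 0] = np.inf
    t_all = means / np.sqrt(var / n)
    out = np.empty(n_perm)
    shape = diffs.shape[1:]
    for p in range(n_perm):
        _, masses = _clusters_and_masses(t_all[p].reshape(shape), thresh)
        out[p] = max((abs(m) for m in masses), default=0.0)
    return out


def cluster_permutation_test(pairs: tuple[np.ndarray, np.ndarray],
                             params: StatsParams | None = None) -> ClusterResult:
    """Dependent-samples cluster permutation test on paired maps."""
    params = params or StatsParams()
    a, b = pairs
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diffs = a - b
    thresh = sstats.t.ppf(1 - params.cluster_alpha / 2, df=n - 1)
    t_map = _paired_t_map(diffs)
    masks, masses = _clusters_and_masses(t_map, thresh)
    rng = np.random.default_rng(params.seed)
    null = _max_null_mass(diffs, thresh, params.n_permutations, rng)
    clusters = []
    for mask, mass in sorted(zip(masks, masses), key=lambda mm: -abs(mm[1])):
        p = (1.0 + float((null >= abs(mass)).sum())) / (params.n_permutations + 1)
        d = cluster_effect_size((a, b), mask)
        clusters.append(Cluster(mask, mass, p, d.value))
    return ClusterResult(clusters, t_map, null, params)


def cluster_effect_size(pairs: tuple[np.ndarray, np.ndarray],
                        mask: np.ndarray) -> EffectSize:
    """Paired Cohen's dz of per-subject means over the cluster bins."""
    if not np.asarray(mask).any():
        raise ValueError("empty cluster mask")
    a, b = pairs
    per_subj = (a - b)[:, mask].mean(axis=1)
    return cohens_d_paired(per_subj, np.zeros_like(per_subj))


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> EffectSize:
    """dz = mean(x - y) / sample SD(x - y); equals t / sqrt(n)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        value = np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else 0.0)
        return EffectSize(EffectKind.COHENS_DZ, value, x.size, degenerate=True)
    return EffectSize(EffectKind.COHENS_DZ, float(d.mean() / sd), x.size)


def rm_anova_2x2(values: np.ndarray) -> dict[str, dict[str, float]]:
    """2x2 within-subject ANOVA via paired contrasts.

    ``values`` is (n_subjects, 4) ordered as CONDITION_ORDER
    (even_ST, even_DT, uneven_ST, uneven_DT).  Each effect reduces to a
    paired t on its contrast: F = t^2 with df (1, n-1) and
    partial eta^2 = F / (F + n - 1).
    """
    values = np.asarray(values, float)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError("values must be (n_subjects, 4)")
    if np.any(~np.isfinite(values)) or values.shape[0] < 3:
        raise ValueError("complete cells for at least 3 subjects required")
    n = values.shape[0]
    e_st, e_dt, u_st, u_dt = values.T
    contrasts = {
        "terrain": 0.5 * (e_st + e_dt) - 0.5 * (u_st + u_dt),
        "task": 0.5 * (e_st + u_st) - 0.5 * (e_dt + u_dt),
        "interaction": (e_st - e_dt) - (u_st - u_dt),
    }
    out = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        t = 0.0 if sd == 0 else c.mean() / (sd / np.sqrt(n))
        F = t ** 2
        p = float(sstats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        out[name] = {"F": float(F), "p": p,
                     "partial_eta_sq": float(F / (F + n - 1)),
                     "df1": 1.0, "df2": float(n - 1)}
    return out


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Wilcoxon signed-rank with zeros discarded.

    T is the sum of ranks of positive differences; R is the matched
    rank-biserial correlation (T+ - T-) / (T+ + T-).  Exact p for n <= 25.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sstats.rankdata(np.abs(d))
    t_pos = float(ranks[d > 0].sum())
    t_neg = float(ranks[d < 0].sum())
    method = "exact" if n <= 25 else "approx"
    p = float(sstats.wilcoxon(d, method=method).pvalue)
    r = (t_pos - t_neg) / (t_pos + t_neg)
    return {"T": t_pos, "p": p, "R": float(r), "n": int(n)}


def holm_correction(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
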