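"""Gait-artifact footprint: five residual-artifact features and distances.

Features, all oriented so that larger = more artifact:

B  explained-variance fraction of the first spectral principal component of
   the gait ERSP
C  lateral / medial channel power ratio (positive-dB values only)
D  neck / non-neck channel power ratio (positive-dB values only)
E  double-support / single-support mean |GPM| ratio
F  walking / standing broadband power ratio (linear units)

Distances between pre-/post-cleaning vectors are Euclidean over
cohort-scaled features (per-feature min-max over all vectors entering the
comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitgpm.montage import ChannelLayout
from gaitgpm.spca import fit_spca
from gaitgpm.timefreq import GPM, GaitERSP

FEATURES = ("B", "C", "D", "E", "F")


@dataclass
class FootprintVector:
    B: float
    C: float
    D: float
    E: float
    F: float
    channel_sets: dict[str, list[str]] = field(default_factory=dict)
    scaling_id: str | None = None  # set by scale_footprints

    def as_array(self) -> np.ndarray:
        return np.array([self.B, self.C, self.D, self.E, self.F], dtype=float)

    def __post_init__(self) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError("footprint features must be finite")
        if not 0.0 <= self.B <= 1.0:
            raise ValueError("feature B is a variance fraction in [0, 1]")


def _positive_ratio(ersp_db: np.ndarray, num_idx: np.ndarray,
                    den_idx: np.ndarray) -> float:
    """Mean positive-dB power over one channel set divided by another.

    An artifact-free map (no positive dB anywhere) yields the neutral
    ratio 1.  A vanishing denominator with non-vanishing numerator is an
    error (the ratio would be unbounded, not meaningfully 'large').
    """
    pos = np.clip(ersp_db, 0.0, None)
    num = pos[num_idx].mean()
    den = pos[den_idx].mean()
    if den == 0.0:
        if num == 0.0:
            return 1.0
        raise ValueError("zero denominator in positive-power ratio")
    return float(num / den)


def double_support_bins(cycles_offsets: dict[str, float], n_bins: int = 100
                        ) -> np.ndarray:
    """Boolean phase-bin mask of double support from average event offsets.

    Double support spans RHS..LTO and LHS..RTO of the cycle.
    """
    centers = (np.arange(n_bins) + 0.5) / n_bins
    lto, lhs, rto = (cycles_offsets[k] for k in ("lto", "lhs", "rto"))
    return ((centers < lto) | ((centers >= lhs) & (centers < rto)))


def compute_footprint(ersp: GaitERSP, gpm: GPM, ds_mask: np.ndarray,
                      layout: ChannelLayout) -> FootprintVector:
    """Five-feature footprint of one subject/pipeline state."""
    sets = layout.sets
    for name in ("lateral", "medial", "neck"):
        if not sets.get(name):
            raise ValueError(f"channel set {name!r} is empty")
    names = ersp.ch_names
    idx = {k: np.array([names.index(c) for c in sets[k] if c in names], dtype=int)
           for k in ("lateral", "medial", "neck")}
    non_neck = np.array([i for i, c in enumerate(names) if c not in sets["neck"]],
                        dtype=int)
    if any(len(v) == 0 for v in idx.values()) or len(non_neck) == 0:
        raise ValueError("channel sets do not overlap the ERSP montage")

    if np.ptp(ersp.values_db) == 0.0:
        B = 0.0  # no spectral variance at all: nothing for a PC to explain
    else:
        B = fit_spca(ersp).explained_fraction_first()
    C = _positive_ratio(ersp.values_db, idx["lateral"], idx["medial"])
    D = _positive_ratio(ersp.values_db, idx["neck"], non_neck)

    ds_mask = np.asarray(ds_mask, dtype=bool)
    if ds_mask.shape[-1] != gpm.values_db.shape[-1]:
        raise ValueError("double-support mask length must equal phase-bin count")
    abs_gpm = np.abs(gpm.values_db)
    ss = abs_gpm[:, :, ~ds_mask].mean()
    if ss == 0:
        E = 1.0 if abs_gpm[:, :, ds_mask].mean() == 0 else np.inf
        if not np.isfinite(E):
            raise ValueError("zero single-support modulation with nonzero double-support")
    else:
        E = float(abs_gpm[:, :, ds_mask].mean() / ss)

    # walking/standing broadband power in linear units; ERSP is dB vs standing
    F = float(np.mean(10.0 ** (ersp.values_db / 10.0)))
    return FootprintVector(B, C, D, E, F,
                           channel_sets={k: list(sets[k]) for k in sets})


def scale_footprints(vectors: list[FootprintVector], scaling_id: str = "cohort-minmax"
                     ) -> list[FootprintVector]:
    """Per-feature min-max scaling to [0, 1] over the cohort."""
    arr = np.vstack([v.as_array() for v in vectors])
    lo = arr.min(axis=0)
    span = arr.max(axis=0) - lo
    span[span == 0] = 1.0
    out = []
    for v, row in zip(vectors, (arr - lo) / span):
        out.append(FootprintVector(*row, channel_sets=v.channel_sets,
                                   scaling_id=scaling_id))
    return out


def footprint_distance(before: FootprintVector, after: FootprintVector) -> float:
    """Euclidean distance between two footprint vectors (same scaling)."""
    if before.scaling_id != after.scaling_id:
        raise ValueError("footprint vectors carry different scalings")
    return float(np.linalg.norm(before.as_array() - after.as_array()))
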