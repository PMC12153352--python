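"""Dyad-aligned repair profiles, 5'->3' strand alignment and combination,
rotational-setting classification, and a raw-count mode for accessibility
(e.g. DNase cleavage) data.

Offsets are measured in plus-strand coordinates relative to the dyad
(position 0); the default window is ±90 with nucleosome-core edges at ±73
(±74..±90 is linker DNA).  ``align_strands`` re-indexes the minus strand by
offset -> -offset so both strands read 5'->3'; ``combine_strands`` is the
unweighted mean of the two aligned strands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gel import Normalizer
from .tracks import LesionTrack

HALF_WINDOW = 90
CORE_EDGE = 73


@dataclass
class DyadProfile:
    offsets: np.ndarray  # -half_window..+half_window
    values: dict[str, np.ndarray]  # strand ('+'/'-') or 'combined' -> value per offset
    n0: dict[str, np.ndarray] | None
    nt: dict[str, np.ndarray] | None
    n_dyads: int
    alignment: str  # 'genomic' | 'aligned' | 'combined'
    mode: str  # 'fraction' | 'count'

    def value(self, strand: str, offset: int) -> float:
        i = int(offset - self.offsets[0])
        return float(self.values[strand][i])


def filter_dyads(dyads: pd.DataFrame, min_score: float = 5.0) -> pd.DataFrame:
    """Strongly positioned nucleosomes: score strictly greater than
    ``min_score``."""
    out = dyads[pd.to_numeric(dyads["score"], errors="coerce") > min_score]
    if len(out) == 0:
        raise ValueError(f"no dyads with score > {min_score}")
    return out.reset_index(drop=True)


def _sum_over_dyads(track: LesionTrack, dyads: pd.DataFrame, offsets: np.ndarray,
                    strand: str) -> np.ndarray:
    """Counts summed over dyads per offset; out-of-range (dyad, offset)
    combinations are skipped."""
    acc = np.zeros(len(offsets), dtype=np.int64)
    for chrom, grp in dyads.groupby("chrom", sort=False):
        arr = track.counts[(chrom, strand)]
        pos = grp["pos"].to_numpy(dtype=np.int64)[:, None] + offsets[None, :]
        ok = (pos >= 1) & (pos <= len(arr))
        vals = np.where(ok, arr[np.clip(pos, 1, len(arr)) - 1], 0)
        acc += vals.sum(axis=0)
    return acc


def dyad_profile(
    track_0: LesionTrack,
    dyads: pd.DataFrame,
    track_t: LesionTrack | None = None,
    normalizer: Normalizer | None = None,
    mode: str = "fraction",
    half_window: int = HALF_WINDOW,
) -> DyadProfile:
    """Per-offset, per-strand profile around nucleosome dyads.

    ``fraction`` mode requires ``track_t`` and a gel-anchored normalizer and
    reports the normalized fraction remaining (counts aggregated over dyads
    before division).  ``count`` mode reports raw summed counts of
    ``track_0`` only (accessibility / initial-damage profiling).
    """
    offsets = np.arange(-half_window, half_window + 1)
    if mode == "fraction":
        if track_t is None or normalizer is None:
            raise ValueError("fraction mode needs track_t and a normalizer")
        n0 = {s: _sum_over_dyads(track_0, dyads, offsets, s) for s in "+-"}
        nt = {s: _sum_over_dyads(track_t, dyads, offsets, s) for s in "+-"}
        values = {s: normalizer.fraction(n0[s], nt[s]) for s in "+-"}
    elif mode == "count":
        n0 = {s: _sum_over_dyads(track_0, dyads, offsets, s) for s in "+-"}
        nt = None
        values = {s: n0[s].astype(float) for s in "+-"}
    else:
        raise ValueError(f"mode must be 'fraction' or 'count', got {mode!r}")
    return DyadProfile(
        offsets=offsets, values=values, n0=n0, nt=nt,
        n_dyads=len(dyads), alignment="genomic", mode=mode,
    )


def align_strands(profile: DyadProfile) -> DyadProfile:
    """Orient the minus strand 5'->3' by re-indexing offset -> -offset.

    The plus strand already reads 5'->3' left to right; applying the flip
    twice restores the genomic profile (involution).
    """
    if profile.alignment == "combined":
        raise ValueError("profile already combined")
    flip = lambda d: None if d is None else {
        s: (v[::-1].copy() if s == "-" else v) for s, v in d.items()
    }
    new_alignment = "aligned" if profile.alignment == "genomic" else "genomic"
    return replace(
        profile,
        values={s: (v[::-1].copy() if s == "-" else v) for s, v in profile.values.items()},
        n0=flip(profile.n0),
        nt=flip(profile.nt),
        alignment=new_alignment,
    )


def combine_strands(profile: DyadProfile) -> DyadProfile:
    """Unweighted per-offset mean of the two 5'->3'-aligned strands."""
    if profile.alignment != "aligned":
        raise ValueError("combine_strands requires a 5'->3'-aligned profile")
    combined = (profile.values["+"] + profile.values["-"]) / 2.0
    add = lambda d: None if d is None else {"combined": d["+"] + d["-"]}
    return replace(
        profile,
        values={"combined": combined},
        n0=add(profile.n0),
        nt=add(profile.nt),
        alignment="combined",
    )


@dataclass
class RotationalFit:
    """Least-squares cosine fit value(o) ≈ a + b cos(2π(o − phase)/period).

    ``phase`` (in [0, period)) marks the fitted maxima.  For a
    fraction-remaining profile, maxima are slow repair = minor-in settings
    and minima are fast repair = minor-out; for an accessibility (count)
    profile the maxima are the accessible minor-out settings.
    """

    mean: float
    amplitude: float
    amplitude_se: float
    phase: float
    period: float
    reliable: bool
    labels: pd.DataFrame | None  # columns: offset, setting

    @property
    def minima_phase(self) -> float:
        return (self.phase + self.period / 2.0) % self.period


def rotational_settings(
    profile: DyadProfile | np.ndarray,
    period: float = 10.3,
    core_edge: int = CORE_EDGE,
    signal: str = "fraction_remaining",
    label_tolerance: float = 2.0,
) -> RotationalFit:
    """Fit the ~10.3-bp rotational-setting periodicity and label offsets.

    Offsets within ``label_tolerance`` bp of a fitted minimum of fraction
    remaining are minor-out (fast repair), within tolerance of a maximum
    minor-in, else intermediate.  For ``signal='accessibility'`` (count-mode
    DNase profiles) the assignment is reversed: cleavage maxima are
    minor-out.  If the fitted amplitude is not distinguishable from zero
    (|b| < 2 SE), labels are withheld and the phase flagged unreliable.
    """
    if isinstance(profile, DyadProfile):
        if profile.alignment == "combined":
            y_all = profile.values["combined"]
        elif len(profile.values) == 1:
            y_all = next(iter(profile.values.values()))
        else:
            raise ValueError("combine strands before fitting rotational settings")
        offsets_all = profile.offsets
    else:
        y_all = np.asarray(profile, dtype=float)
        offsets_all = np.arange(-(len(y_all) // 2), len(y_all) - len(y_all) // 2)
    keep = (np.abs(offsets_all) <= core_edge) & np.isfinite(y_all)
    o = offsets_all[keep].astype(float)
    y = y_all[keep]
    if len(o) < 8:
        raise ValueError("too few finite offsets inside the core to fit")
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(o), np.cos(w * o), np.sin(w * o)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(o) - 3, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    a, c1, c2 = beta
    b = float(np.hypot(c1, c2))
    if b > 0:
        grad = np.array([0.0, c1 / b, c2 / b])
        b_se = float(np.sqrt(grad @ cov @ grad))
    else:
        b_se = float(np.sqrt(max(cov[1, 1], cov[2, 2])))
    phase = float((np.arctan2(c2, c1) / w) % period)
    reliable = b >= 2.0 * b_se
    labels = None
    if reliable:
        if signal == "fraction_remaining":
            minor_in_phase, minor_out_phase = phase, (phase + period / 2) % period
        elif signal == "accessibility":
            minor_out_phase, minor_in_phase = phase, (phase + period / 2) % period
        else:
            raise ValueError(f"unknown signal kind {signal!r}")

        def circ_dist(x, ref):
            d = np.abs((x - ref) % period)
            return np.minimum(d, period - d)

        offs = offsets_all[np.abs(offsets_all) <= core_edge].astype(float)
        setting = np.full(len(offs), "intermediate", dtype=object)
        setting[circ_dist(offs, minor_out_phase) <= label_tolerance] = "minor-out"
        setting[circ_dist(offs, minor_in_phase) <= label_tolerance] = "minor-in"
        labels = pd.DataFrame({"offset": offs.astype(int), "setting": setting})
    return RotationalFit(
        mean=float(a), amplitude=b, amplitude_se=b_se, phase=phase,
        period=period, reliable=reliable, labels=labels,
    )


def asymmetry_index(profile: DyadProfile, inner: int = 10, outer: int = 50) -> float:
    """Mean value over offsets [+inner, +outer] minus mean over
    [-outer, -inner] on a 5'->3'-aligned combined profile; positive means
    slower repair (more CPDs remaining) on the 3' side."""
    if profile.alignment != "combined":
        raise ValueError("asymmetry_index requires an aligned, combined profile")
    v = profile.values["combined"]
    off = profile.offsets
    right = v[(off >= inner) & (off <= outer)]
    left = v[(off >= -outer) & (off <= -inner)]
    return float(np.nanmean(right) - np.nanmean(left))
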