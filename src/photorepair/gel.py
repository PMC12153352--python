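"""Alkaline-gel quantification of bulk CPD repair and gel-anchored
normalization of per-site repair fractions.

The T4 endonuclease V assay cleaves DNA at CPDs; under random (Poisson)
cleavage the expected breaks per nucleotide equal the reciprocal of the
number-average fragment length, so the lesion density is

    phi (CPDs/kb) = 1000 * (1/L_t4 - 1/L_mock)

and percent repaired at time t is R(t) = 100 * (1 - phi_t / phi_0) relative
to the 0-h-UV lane.  The gel-measured genome-wide fraction remaining
F_gel(t) = 1 - R(t)/100 anchors the sequencing-based per-site repair
fractions: with depth-normalized per-site ratio
r_i = (n_i(t)/N_t) / (n_i(0)/N_0), the normalized fraction remaining is
f_i = F_gel(t) * r_i, so the genome-wide normalized fraction equals
F_gel(t) by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tracks import LesionTrack


@dataclass
class GelLane:
    """One gel lane: either raw fragment lengths (simulated lanes) or a
    densitometry migration profile plus ladder calibration points."""

    lane: str
    treatment: str  # "t4" or "mock"
    timepoint: float
    fragment_lengths: np.ndarray | None = None
    profile: pd.DataFrame | None = None  # columns: distance_mm, intensity
    ladder: pd.DataFrame | None = None  # columns: distance_mm, length

    def __post_init__(self):
        if self.treatment not in ("t4", "mock"):
            raise ValueError(f"treatment must be 't4' or 'mock', got {self.treatment!r}")
        if self.fragment_lengths is None and self.profile is None:
            raise ValueError("lane needs fragment_lengths or a migration profile")
        if self.profile is not None and (self.ladder is None or len(self.ladder) < 2):
            raise ValueError("migration profile requires a ladder with >= 2 points")


def lane_fragment_length(lane: GelLane) -> float:
    """Representative fragment length (nt) of a lane.

    Simulated lanes return the number-average of the raw fragment lengths.
    Densitometry lanes return the migration distance at the lane's median
    cumulative intensity converted to length by log-linear interpolation of
    the ladder; a median outside the ladder range is an error (no
    extrapolation).
    """
    if lane.fragment_lengths is not None:
        lengths = np.asarray(lane.fragment_lengths, dtype=float)
        if (lengths <= 0).any():
            raise ValueError("fragment lengths must be positive")
        return float(lengths.mean())
    prof = lane.profile.sort_values("distance_mm")
    dist = prof["distance_mm"].to_numpy(dtype=float)
    inten = prof["intensity"].to_numpy(dtype=float)
    cum = np.cumsum(inten)
    if cum[-1] <= 0:
        raise ValueError("lane has no signal")
    median_dist = float(np.interp(cum[-1] / 2.0, cum, dist))
    lad = lane.ladder.sort_values("distance_mm")
    ld = lad["distance_mm"].to_numpy(dtype=float)
    ll = np.log(lad["length"].to_numpy(dtype=float))
    if not (ld[0] <= median_dist <= ld[-1]):
        raise ValueError(
            f"median migration {median_dist:.2f} mm outside ladder range "
            f"[{ld[0]:.2f}, {ld[-1]:.2f}]"
        )
    return float(np.exp(np.interp(median_dist, ld, ll)))


def cpds_per_kb(length_t4: float, length_mock: float) -> float:
    """Lesion density phi (CPDs/kb) from T4-endoV and mock lane lengths."""
    if length_t4 <= 0 or length_mock <= 0:
        raise ValueError("fragment lengths must be > 0")
    phi = 1000.0 * (1.0 / length_t4 - 1.0 / length_mock)
    if phi < 0:
        warnings.warn("T4 lane fragments longer than mock; clamping density to 0")
        return 0.0
    return phi


def percent_repaired(phi_t: float, phi_0: float) -> float:
    """R(t) = 100 * (1 - phi_t / phi_0) relative to the 0-h-UV density."""
    if phi_0 <= 0:
        raise ValueError("phi_0 must be > 0 (no damage induced)")
    r = 100.0 * (1.0 - phi_t / phi_0)
    if r < 0:
        warnings.warn(f"negative percent repaired ({r:.2f}%)")
    return r


def repair_summary(lanes: list[GelLane]) -> pd.DataFrame:
    """Per-timepoint lesion density, percent repaired and gel fraction
    remaining, using matched T4/mock lanes; R is taken relative to the
    earliest (0) timepoint."""
    by_t: dict[float, dict[str, float]] = {}
    for lane in lanes:
        by_t.setdefault(lane.timepoint, {})[lane.treatment] = lane_fragment_length(lane)
    rows = []
    for t in sorted(by_t):
        d = by_t[t]
        if "t4" not in d or "mock" not in d:
            raise ValueError(f"timepoint {t} is missing a t4 or mock lane")
        rows.append({"timepoint": t, "phi_cpds_per_kb": cpds_per_kb(d["t4"], d["mock"])})
    out = pd.DataFrame(rows)
    phi0 = out.loc[out["timepoint"].idxmin(), "phi_cpds_per_kb"]
    out["percent_repaired"] = [percent_repaired(p, phi0) for p in out["phi_cpds_per_kb"]]
    out["fraction_remaining"] = np.clip(1.0 - out["percent_repaired"] / 100.0, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

def holm_sidak(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Holm-Šidák step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def replicate_test(groups: dict[str, np.ndarray | list]) -> pd.DataFrame:
    """All pairwise unpaired t-tests across replicate groups with Holm-Šidák
    correction.

    Identical zero-variance groups compare at p = 1.
    """
    names = list(groups)
    if any(len(np.atleast_1d(groups[n])) < 2 for n in names):
        raise ValueError("each group needs >= 2 replicates")
    rows = []
    for a, b in combinations(names, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0 and xa.mean() == xb.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(xa, xb).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"group_a": a, "group_b": b, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# gel anchoring of sequencing repair fractions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Normalizer:
    """Gel-anchored fraction-remaining normalizer for one timepoint.

    ``fraction(n0, nt)`` maps aggregated counts (sum counts over a region at
    both timepoints, then divide) to the normalized fraction of CPDs
    remaining: F_gel * (nt/N_t)/(n0/N_0).
    """

    f_gel: float
    n0_total: int
    nt_total: int

    def fraction(self, n0, nt):
        n0 = np.asarray(n0, dtype=float)
        nt = np.asarray(nt, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (nt / self.nt_total) / (n0 / self.n0_total)
        out = self.f_gel * r
        out = np.where(n0 > 0, out, np.nan)
        return float(out) if out.ndim == 0 else out


def gel_anchor(track_0: LesionTrack, track_t: LesionTrack, f_gel: float) -> Normalizer:
    """Build the normalizer anchoring depth-normalized per-site ratios to the
    gel-measured genome-wide fraction remaining F_gel(t)."""
    if not (0.0 <= f_gel <= 1.0):
        raise ValueError("F_gel must be in [0, 1]")
    if set(track_0.counts) != set(track_t.counts):
        raise ValueError("tracks do not share genome/strand keys")
    n0, nt = track_0.N, track_t.N
    if n0 <= 0 or nt <= 0:
        raise ValueError("both tracks need positive totals")
    return Normalizer(f_gel=f_gel, n0_total=n0, nt_total=nt)


def per_site_fraction(
    track_0: LesionTrack, track_t: LesionTrack, normalizer: Normalizer
) -> dict[tuple[str, str], np.ndarray]:
    """Per-position normalized fraction remaining; NaN where n(0) = 0."""
    return {
        key: normalizer.fraction(track_0.counts[key], track_t.counts[key])
        for key in track_0.counts
    }
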