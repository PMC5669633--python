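"""Pause sites, pause durations, initiation frequencies and the
pause-initiation limit.

mNET-seq maps the RNA 3'-end held by transcribing Pol II, so its coverage is
proportional to polymerase occupancy: I/v in the gene body plus I*d
polymerase equivalents dwelling at the pause site.  The pause site m* is the
position of maximal signal within the first exon, accepted when it exceeds
5x the window median.  The productive initiation frequency I (equal to the
pause release rate at steady state) comes from TT-seq signal over non-first
constitutive exons converted to absolute RNA per cell via the spike-in
factor kappa:

    I_i = (1/kappa) * tb_i / (t_lab * L_i,exonic)

Pause durations divide the pause-window occupancy by I; a single cohort
scale factor — median_i I_i (t*-t) / sum_rw p_im, the dimensional reading in
which the elongation velocity cancels — converts mNET signal units into
polymerase counts.  The steric limit 200 bp / (d*I) >= 50 bp flags
impossible (d, I) combinations: initiation cannot outpace pause-window
throughput when polymerases closer than 50 bp collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LimitConfig:
    """Constants of the pause window and steric limit."""

    pause_window_halfwidth: float = 100.0  # bp
    steric_distance: float = 50.0          # bp
    pause_peak_fold: float = 5.0

    def __post_init__(self) -> None:
        if min(self.pause_window_halfwidth, self.steric_distance, self.pause_peak_fold) <= 0:
            raise ValueError("all limit constants must be positive")

    @property
    def pause_window(self) -> float:
        return 2 * self.pause_window_halfwidth


def detect_pause_site(signal: np.ndarray, fold: float = 5.0) -> tuple[int, float] | None:
    """Pause site m* and strength rho from mNET-seq signal over the
    TU-local window [TSS, first_exon_end - 5 bp).

    The maximum is reported only when it exceeds ``fold`` times the window
    median (computed over all non-negative values, zeros included); ties
    break to the 5'-most maximum.  Windows shorter than 20 bp are an error.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.size < 20:
        raise ValueError("pause-site window shorter than 20 bp")
    if (sig < 0).any():
        raise ValueError("pause detection expects a non-negative (corrected) track")
    m = int(np.argmax(sig))
    rho = float(sig[m])
    med = float(np.median(sig))
    if rho <= 0 or rho <= fold * med:
        return None
    return m, rho


def pause_window_bounds(m_star: int, halfwidth: float = 100.0) -> tuple[int, int]:
    """TU-local pause window: +-halfwidth around m*, or the first
    2*halfwidth bases when m* lies within halfwidth of the TSS."""
    h = int(halfwidth)
    if m_star < h:
        return 0, 2 * h
    return m_star - h, m_star + h


def initiation_frequency(
    tb_exonic: float, kappa: float, t_lab: float, exonic_length: float
) -> float:
    """Productive initiation frequency I (cell^-1 min^-1) from TT-seq signal
    restricted to non-first constitutive exons."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if exonic_length <= 0:
        raise ValueError("no non-first constitutive exonic bases")
    return tb_exonic / (kappa * t_lab * exonic_length)


def pause_scale_factor(
    initiation: np.ndarray,
    rw_sums: np.ndarray,
    t_star: float = 15.0,
    t_lab: float = 5.0,
    robust_quantile: float = 0.5,
) -> float:
    """Polymerases per mNET signal unit.

    For each TU the expected number of polymerases traversing its response
    window during t*-t minutes is I_i * (t*-t); dividing by the observed
    mNET response-window sum and taking the median over TUs above the
    ``robust_quantile`` of mNET signal gives the cohort conversion factor.
    (In the full expression the CDK9-derived velocity v_i cancels.)
    """
    I = np.asarray(initiation, dtype=float)
    s = np.asarray(rw_sums, dtype=float)
    ok = np.isfinite(I) & np.isfinite(s) & (s > 0)
    if robust_quantile > 0 and ok.sum() > 1:
        ok &= s >= np.quantile(s[ok], robust_quantile)
    if not ok.any():
        raise ValueError("no TU eligible for the pause scale factor")
    return float(np.median(I[ok] * (t_star - t_lab) / s[ok]))


def pause_duration(pause_sum: float, initiation: float, scale: float) -> float:
    """Pause duration d (min): occupancy in the +-100 bp pause window,
    converted to polymerases, divided by the pause release rate I."""
    if initiation <= 0:
        raise ValueError("pause duration undefined for I <= 0")
    return pause_sum / initiation * scale


def pause_duration_noI(
    pause_sum: float, rw_sum: float, l_rw: float, v_hat: float
) -> float | None:
    """Initiation-free pause duration d_hat (min):
    d_hat = sum_pause p * L_rw / (sum_rw p * v_hat).

    Up to a single cohort proportionality constant this matches d; use
    :func:`dhat_display_factor` to align the distributions.
    """
    if rw_sum <= 0 or v_hat <= 0:
        return None
    return pause_sum * l_rw / (rw_sum * v_hat)


def dhat_display_factor(d: np.ndarray, dhat: np.ndarray) -> float:
    """Single proportionality constant median(d)/median(d_hat) over TUs with
    both estimates (display alignment only)."""
    d = np.asarray(d, dtype=float)
    dh = np.asarray(dhat, dtype=float)
    ok = np.isfinite(d) & np.isfinite(dh) & (dh > 0)
    if not ok.any():
        return float("nan")
    return float(np.median(d[ok]) / np.median(dh[ok]))


def limit_check(d: float, initiation: float, config: LimitConfig | None = None) -> tuple[float, bool]:
    """Margin to the pause-initiation limit and violation flag.

    margin = (pause_window / (d*I)) / steric_distance; a margin below 1
    means the combination of pause duration and initiation frequency would
    require initiating polymerases closer than the steric distance.
    """
    config = config or LimitConfig()
    if d <= 0 or initiation <= 0:
        raise ValueError("d and I must be positive")
    margin = (config.pause_window / (d * initiation)) / config.steric_distance
    return margin, margin < 1.0
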