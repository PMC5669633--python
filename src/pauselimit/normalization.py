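"""Spike-in based normalization of nascent-RNA sequencing samples.

Three per-sample quantities are derived here:

* ``c`` — the antisense bias ratio: the fraction of spurious opposite-strand
  reads introduced by reverse transcription, estimated per sample as the
  median antisense/sense count ratio over spike-ins;
* ``sigma`` — a median-of-ratios size factor correcting library size and
  sequencing-depth variation, computed on long TUs trimmed at both ends so
  the CDK9-inhibition response cannot leak into the normalization;
* ``kappa`` — the conversion factor from transcribed-base signal to absolute
  RNA amount per cell, anchored on the known molar amounts of labeled
  spike-ins.

An underestimated RNA-extraction efficiency scales ``kappa`` down and all
initiation frequencies up by the same factor; absolute initiation
frequencies therefore inherit the spike-in mass/cell-count accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import CountTable

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214085774e23  # 1/mol

# monomer masses of the 5'-monophosphate residues, g/mol
_MASS = {"A": 329.2, "U": 306.2, "C": 305.2, "G": 345.2}
_MASS_4SU = 322.26
_TRIPHOSPHATE = 159.0


@dataclass
class SampleNormalization:
    sample_id: str
    antisense_bias_c: float
    size_factor_sigma: float = 1.0
    conversion_kappa: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.antisense_bias_c < 1:
            raise ValueError("antisense bias ratio must lie in [0, 1)")
        if self.size_factor_sigma <= 0:
            raise ValueError("size factor must be positive")


def antisense_bias_ratio(counts: CountTable) -> pd.Series:
    """Per-sample antisense bias ratio c_j = median_i antisense/sense over
    spike-ins with nonzero sense counts.

    Raises if a sample has no spike-in with sense counts, or if the ratio
    reaches 1 (which indicates swapped strand tracks).
    """
    out = {}
    for sample in counts.samples:
        s = counts.sense[sample].to_numpy(dtype=float)
        a = counts.antisense[sample].to_numpy(dtype=float)
        ok = s > 0
        if not ok.any():
            raise ValueError(f"{sample}: no spike-in with sense counts > 0")
        c = float(np.median(a[ok] / s[ok]))
        if c >= 1:
            raise ValueError(
                f"{sample}: antisense bias ratio {c:.2f} >= 1; are the strand tracks swapped?"
            )
        out[sample] = c
    return pd.Series(out, name="antisense_bias_c")


def corrected_counts(sense, antisense, c: float):
    """Real (bias-corrected) counts s = (S - c*A) / (1 - c^2).

    The observed sense signal S mixes the true sense signal with a fraction
    ``c`` of the true antisense signal (and vice versa); the transform
    inverts that mixing.  Negative results are clamped to 0 (logged).
    """
    if not 0 <= c < 1:
        raise ValueError("antisense bias ratio must lie in [0, 1)")
    s = (np.asarray(sense, dtype=float) - c * np.asarray(antisense, dtype=float)) / (1 - c * c)
    n_neg = int(np.sum(s < 0))
    if n_neg:
        logger.debug("corrected_counts: clamped %d negative values to 0", n_neg)
    return np.maximum(s, 0.0) if s.ndim else float(max(s, 0.0))


def size_factors(tb: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over a TU x sample transcribed-base
    matrix: sigma_j = median_i tb_ij / geomean_j' tb_ij'.

    TUs containing a zero in any sample are excluded (the geometric mean is
    undefined there).  Raises if no TU is eligible.
    """
    mat = tb.to_numpy(dtype=float)
    ok = (mat > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no TU with positive transcribed bases in all samples")
    mat = mat[ok]
    log_gm = np.mean(np.log(mat), axis=1, keepdims=True)
    sigma = np.exp(np.median(np.log(mat) - log_gm, axis=0))
    return pd.Series(sigma, index=tb.columns, name="size_factor_sigma")


def mnet_size_factors(
    tb: pd.DataFrame, response_ratios: pd.Series, threshold: float = 0.05
) -> pd.Series:
    """Size factors restricted to non-responder TUs (r_i < threshold).

    mNET-seq occupancy shifts globally when pause release is blocked, so its
    size factors are anchored on TUs whose TT-seq response to CDK9
    inhibition is below ``threshold``.
    """
    nonresp = response_ratios.index[response_ratios < threshold]
    eligible = tb.index.intersection(nonresp)
    if eligible.empty:
        raise ValueError(
            f"no non-responder TU with r < {threshold}; consider raising the threshold"
        )
    return size_factors(tb.loc[eligible])


def molar_mass(sequence: str, labeled: bool, tau: float = 0.1) -> float:
    """Molecular weight (g/mol) of a 5'-triphosphate RNA.

    For labeled spike-ins a fraction ``tau`` of uracil positions carries the
    4-thiouracil mass (322.26) instead of the uracil mass.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGU"}
    if sum(counts.values()) != len(seq):
        bad = sorted(set(seq) - set("ACGU"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    t = tau if labeled else 0.0
    mass = (
        counts["A"] * _MASS["A"]
        + (1 - t) * counts["U"] * _MASS["U"]
        + counts["C"] * _MASS["C"]
        + counts["G"] * _MASS["G"]
        + t * counts["U"] * _MASS_4SU
        + _TRIPHOSPHATE
    )
    return float(mass)


def spikein_molecules_per_cell(mass_g: float, n_cells: float, molar_mass_g_mol: float) -> float:
    """Number of spike-in molecules per cell, N = m * N_A / (M * n)."""
    if mass_g <= 0 or n_cells <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("mass, cell number and molar mass must be positive")
    return mass_g * AVOGADRO / (molar_mass_g_mol * n_cells)


def conversion_factor(
    tb: pd.DataFrame,
    lengths: pd.Series,
    molecules_per_cell: pd.Series,
    labeled: pd.Series,
) -> float:
    """Conversion factor kappa to RNA amount per cell:
    mean over samples of median over labeled spike-ins of tb / (L * N).

    ``tb`` is the spike-in transcribed-base matrix (size-factor scaled),
    indexed like ``lengths``/``molecules_per_cell``/``labeled``.
    """
    idx = tb.index[labeled.reindex(tb.index).fillna(False).astype(bool)]
    sub = tb.loc[idx]
    if sub.empty or not (sub.to_numpy() > 0).any():
        raise ValueError("need at least one labeled spike-in with positive tb")
    denom = (lengths.loc[idx] * molecules_per_cell.loc[idx]).to_numpy(dtype=float)
    per_sample = np.median(sub.to_numpy(dtype=float) / denom[:, None], axis=0)
    return float(np.mean(per_sample))
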