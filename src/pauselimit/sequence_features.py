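"""Sequence and structure covariates of promoter-proximal pausing.

Pausing correlates with the stability of the 8-bp DNA-RNA hybrid in the
Pol II active centre: melting-temperature profiles are computed by tiling
the sequence with 8-mer duplexes under nearest-neighbor thermodynamics.
Two parameter sets are shipped inline: the DNA/DNA unified table
(SantaLucia 1998) and the RNA/DNA hybrid table (Sugimoto et al. 1995), both
at 1 M monovalent salt; strand concentration defaults to 1 uM.

Also here: the position weight matrix of bases around called pause sites
(cohort-scale data show a strongly conserved C at the RNA 3'-end) and
DMS-seq structure-signal normalization against a denatured control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAS_CONSTANT = 1.987  # cal / (mol K)

# DNA/DNA unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K),
# 1 M NaCl; keys are the top-strand dinucleotide 5'->3'.
_DNA_DNA = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_DNA_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "C": (0.1, -2.8), "G": (0.1, -2.8)}

# RNA/DNA hybrid nearest-neighbor parameters (Sugimoto 1995), keyed by the
# RNA strand dinucleotide 5'->3' (DNA strand is its complement).
_RNA_DNA = {
    "AA": (-7.8, -21.9), "AC": (-5.9, -12.3), "AG": (-9.1, -23.5), "AU": (-8.3, -23.9),
    "CA": (-9.0, -26.1), "CC": (-9.3, -23.2), "CG": (-16.3, -47.1), "CU": (-7.0, -19.7),
    "GA": (-5.5, -13.5), "GC": (-8.0, -17.1), "GG": (-12.8, -31.9), "GU": (-7.8, -21.6),
    "UA": (-7.8, -23.2), "UC": (-8.6, -22.9), "UG": (-10.4, -28.4), "UU": (-11.5, -36.4),
}
_RNA_DNA_INIT = (1.9, -3.9)  # duplex initiation, both ends combined


@dataclass
class TmProfile:
    """Melting temperatures (deg C) of k-mer duplexes tiling a sequence;
    position i holds the duplex starting at TU-local position i."""

    positions: np.ndarray
    tm: np.ndarray
    duplex: str


def _duplex_tm(seq: str, duplex: str, strand_conc: float) -> float:
    dh = 0.0
    ds = 0.0
    if duplex == "dna_dna":
        for i in range(len(seq) - 1):
            h, s = _DNA_DNA[seq[i: i + 2]]
            dh += h
            ds += s
        for base in (seq[0], seq[-1]):
            h, s = _DNA_INIT[base]
            dh += h
            ds += s
    else:
        rna = seq.replace("T", "U")
        for i in range(len(rna) - 1):
            h, s = _RNA_DNA[rna[i: i + 2]]
            dh += h
            ds += s
        dh += _RNA_DNA_INIT[0]
        ds += _RNA_DNA_INIT[1]
    # non-self-complementary duplex at total strand concentration C_T
    return dh * 1000.0 / (ds + GAS_CONSTANT * math.log(strand_conc / 4.0)) - 273.15


def tm_profile(
    sequence: str,
    duplex: str = "dna_rna",
    k: int = 8,
    strand_conc: float = 1e-6,
) -> TmProfile:
    """Nearest-neighbor melting temperature of every k-mer duplex along the
    sequence (sense strand, 5'->3').  Positions whose k-mer contains an
    ambiguous base are skipped with a log message (NaN in the profile)."""
    if duplex not in ("dna_rna", "dna_dna"):
        raise ValueError("duplex must be 'dna_rna' or 'dna_dna'")
    seq = sequence.upper().replace("U", "T")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than {k} bases")
    n = len(seq) - k + 1
    tm = np.full(n, np.nan)
    for i in range(n):
        kmer = seq[i: i + k]
        if any(b not in "ACGT" for b in kmer):
            logger.debug("tm_profile: ambiguous base in window at %d, skipped", i)
            continue
        tm[i] = _duplex_tm(kmer, duplex, strand_conc)
    return TmProfile(positions=np.arange(n), tm=tm, duplex=duplex)


# ---------------------------------------------------------------------------
# pause-site PWM
# ---------------------------------------------------------------------------

PWM_FLANK = 10  # positions -10..+10 around the pause site


def pause_pwm(sequences: list[str], pseudocount: float = 0.25) -> pd.DataFrame:
    """Position weight matrix of bases around called pause sites.

    Input sequences must all have length 2*PWM_FLANK + 1 (position 0 = the
    pause site, i.e. the RNA 3'-end base), sense strand.  Returns a
    (positions x ACGT) frame of probabilities; columns of each position sum
    to 1.
    """
    width = 2 * PWM_FLANK + 1
    if not sequences:
        raise ValueError("need at least one sequence")
    counts = np.full((width, 4), pseudocount)
    order = {b: i for i, b in enumerate("ACGT")}
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        if len(s) != width:
            raise ValueError(f"sequence length {len(s)} != {width}")
        for i, b in enumerate(s):
            if b in order:
                counts[i, order[b]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, index=np.arange(-PWM_FLANK, PWM_FLANK + 1), columns=list("ACGT"))


def write_meme(pwm: pd.DataFrame, path, name: str = "pause_site") -> None:
    """Write a PWM in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)}\n")
        for _, row in pwm.iterrows():
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# DMS-seq structure signal
# ---------------------------------------------------------------------------

def dms_normalize(
    invivo: np.ndarray,
    denatured: np.ndarray,
    initiation: float = 1.0,
    max_negative_frac: float = 0.05,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Depth-adjusted in vivo structure signal over a window (typically
    [-65, -15] bp upstream of the pause site).

    The denatured reference is scaled by the largest factor alpha in (0, 1]
    such that at most ``max_negative_frac`` of window positions go negative
    after subtraction (alpha found by bisection); negatives are then set to
    0 and the window mean is divided by the initiation frequency.

    Returns ``(mean_signal, alpha)``.  An all-zero denatured track yields
    the raw in vivo mean with a warning (alpha = 0).
    """
    iv = np.asarray(invivo, dtype=float)
    de = np.asarray(denatured, dtype=float)
    if iv.shape != de.shape:
        raise ValueError("in vivo and denatured windows must align")
    if not (de > 0).any():
        logger.warning("dms_normalize: denatured track is all zero; returning raw mean")
        return float(np.mean(iv) / initiation), 0.0

    def neg_frac(alpha: float) -> float:
        return float(np.mean(iv - alpha * de < 0))

    alpha = 1.0
    if neg_frac(1.0) > max_negative_frac:
        lo, hi = 0.0, 1.0  # neg_frac is nondecreasing in alpha
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if neg_frac(mid) > max_negative_frac:
                hi = mid
            else:
                lo = mid
        alpha = lo
    resid = np.maximum(iv - alpha * de, 0.0)
    return float(resid.mean() / initiation), alpha
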