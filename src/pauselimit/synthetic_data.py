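"""Synthetic TT-seq / mNET-seq experiments with known kinetic ground truth.

The generator produces complete cohorts — TU annotation, strand-specific
TT-seq and mNET-seq coverage for control and CDK9-inhibited conditions (two
replicates each), spike-in counts and a truth table — from per-TU kinetic
parameters: initiation frequency I (polymerases cell^-1 min^-1), a pause
site with dwell time d (min), a body elongation velocity v (bp/min) and a
CDK9 response ratio r.

TT-seq model.  Polymerases initiate as a Poisson process at rate I and move
along a piecewise-constant velocity profile; the pause is a 1-bp segment of
velocity 1/d.  A polymerase of age s at harvest contributes one labeled
fragment spanning [tau(max(s - t_lab, 0)), tau(s)), where tau integrates the
velocity profile; the fragment's contribution is weighted by the uracil-
dependent labeling bias 1 - (1 - p_lab)^{#u} (#u = round(0.28 * length)) and
by a logistic size-selection weight centred at 80 bp.  Under CDK9
inhibition, initiation into productive elongation during the final t*
minutes is reduced by the response ratio r, depleting the labeled signal in
a response window of width ~ v * (t* - t_lab) downstream of the pause site.
Two thinning modes are provided (see docs/methods.md): ``"sharp"`` (default)
removes, with probability r, the fragment mass inside the response window —
the data-generating process of the response-window model the estimators are
built on; ``"kinetic"`` thins whole polymerases by their release age, which
smears the window edge over one labeling duration.

mNET-seq model.  Steady-state occupancy at a position is I / v(x) — the
polymerase dwell per base — so the pause contributes I*d polymerase
equivalents, deposited with a Gaussian spread (sd 20 bp) around the pause
site.  Under inhibition the pause dwell rises to d_inh and the gene-body
flux drops to I*(1 - r) within reach of the treatment.

Spike-ins follow the molar-mass model: sense counts are proportional to
N * L molecules per cell, antisense counts arise at the bleed-through rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    CountTable,
    GeneModel,
    StrandedCoverage,
    write_bedgraph,
    write_chrom_sizes,
    write_gtf,
)
from .normalization import molar_mass, spikein_molecules_per_cell

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# global simulation constants
# ---------------------------------------------------------------------------

@dataclass
class GlobalSimParams:
    """Cohort-level constants of the simulated experiment.

    Times are minutes, positions bp.  ``kappa_true`` converts RNA molecules
    per cell into expected TT-seq coverage (the quantity the spike-in
    conversion factor recovers); ``mnet_depth`` converts polymerase
    occupancy into expected mNET-seq counts.
    """

    labeling_duration: float = 5.0       # t_lab
    treatment_duration: float = 15.0     # t*
    labeling_probability: float = 0.05   # p_lab, per uracil
    uracil_fraction: float = 0.28
    size_selection_midpoint: float = 80.0
    size_selection_scale: float = 10.0
    antisense_bleed: float = 0.025       # c_true
    kappa_true: float = 20.0
    mnet_depth: float = 50.0
    pause_read_sd: float = 20.0
    steric_occupancy_cap: float = 4.0    # max polymerases per 200-bp pause window
    sonication_mean_bp: float = 200.0    # mean sequenced-fragment length
    thinning: str = "sharp"              # or "kinetic"
    spike_mass_g: float = 25e-9
    spike_cells: float = 3.27e7
    depth_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.labeling_probability <= 1:
            raise ValueError("labeling probability must lie in [0, 1]")
        if self.treatment_duration <= self.labeling_duration:
            raise ValueError("treatment duration must exceed labeling duration")
        if self.thinning not in ("sharp", "kinetic"):
            raise ValueError("thinning must be 'sharp' or 'kinetic'")


TT_SAMPLES = [
    ("tt_control_1", "control", 1),
    ("tt_control_2", "control", 2),
    ("tt_inhibited_1", "inhibited", 1),
    ("tt_inhibited_2", "inhibited", 2),
]
MNET_SAMPLES = [
    ("mnet_control_1", "control", 1),
    ("mnet_control_2", "control", 2),
    ("mnet_inhibited_1", "inhibited", 1),
    ("mnet_inhibited_2", "inhibited", 2),
]

_DEFAULT_DEPTHS = {
    "tt_control_1": 1.00, "tt_control_2": 1.12,
    "tt_inhibited_1": 0.93, "tt_inhibited_2": 1.05,
    "mnet_control_1": 1.00, "mnet_control_2": 1.10,
    "mnet_inhibited_1": 0.95, "mnet_inhibited_2": 1.08,
}


# ---------------------------------------------------------------------------
# velocity profiles and elementary operations
# ---------------------------------------------------------------------------

class VelocityProfile:
    """Piecewise-constant elongation velocity along a TU.

    A pause is a 1-bp segment with velocity 1/d bp/min (dwell d) at the
    pause position.  The last segment extends indefinitely so polymerases
    can run past the annotated TU end.
    """

    def __init__(self, breaks: Sequence[float], velocities: Sequence[float]):
        self.breaks = np.asarray(breaks, dtype=float)
        self.velocities = np.asarray(velocities, dtype=float)
        if self.breaks.size != self.velocities.size:
            raise ValueError("need one velocity per segment start")
        if self.breaks[0] != 0 or np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must start at 0 and increase")
        if np.any(self.velocities <= 0):
            raise ValueError("velocities must be positive")
        seg_len = np.diff(self.breaks)
        seg_time = seg_len / self.velocities[:-1]
        self._t_at_break = np.concatenate(([0.0], np.cumsum(seg_time)))

    @classmethod
    def with_pause(cls, body_velocity: float, pause_position: float | None,
                   pause_duration: float, pause_width: float = 1.0) -> "VelocityProfile":
        if pause_position is None or pause_duration <= 0:
            return cls([0.0], [body_velocity])
        return cls(
            [0.0, float(pause_position), float(pause_position) + pause_width],
            [body_velocity, pause_width / pause_duration, body_velocity],
        )

    def position(self, t):
        """tau(t): bp elongated after t minutes from the TSS."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        k = np.clip(np.searchsorted(self._t_at_break, t, side="right") - 1, 0, len(self.breaks) - 1)
        pos = self.breaks[k] + (t - self._t_at_break[k]) * self.velocities[k]
        return pos if pos.ndim else float(pos)

    def time_at(self, x):
        """Inverse of :meth:`position`: minutes to reach position x (entry
        time where x falls inside the pause)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("position must be non-negative")
        k = np.clip(np.searchsorted(self.breaks, x, side="right") - 1, 0, len(self.breaks) - 1)
        t = self._t_at_break[k] + (x - self.breaks[k]) / self.velocities[k]
        return t if t.ndim else float(t)

    def velocity_at(self, x):
        x = np.asarray(x, dtype=float)
        k = np.clip(np.searchsorted(self.breaks, x, side="right") - 1, 0, len(self.breaks) - 1)
        v = self.velocities[k]
        return v if v.ndim else float(v)


def elongation_position(profile: VelocityProfile, t: float):
    """Position (bp) reached by a polymerase after t minutes."""
    return profile.position(t)


def labeling_bias(fragment_length, p_lab: float = 0.05, uracil_fraction: float = 0.28):
    """Uracil-content dependent labeling probability
    l_f = 1 - (1 - p_lab)^{#u}, with #u = round(uracil_fraction * length)."""
    if not 0 <= p_lab <= 1:
        raise ValueError("labeling probability must lie in [0, 1]")
    n_u = np.round(uracil_fraction * np.maximum(np.asarray(fragment_length, dtype=float), 0.0))
    out = 1.0 - (1.0 - p_lab) ** n_u
    return out if out.ndim else float(out)


def size_selection_weight(fragment_length, midpoint: float = 80.0, scale: float = 10.0):
    """Logistic size-selection weight 1 / (1 + exp(-(len - midpoint)/scale))."""
    if midpoint <= 0 or scale <= 0:
        raise ValueError("midpoint and scale must be positive")
    z = (np.asarray(fragment_length, dtype=float) - midpoint) / scale
    out = 1.0 / (1.0 + np.exp(-z))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# per-TU ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTU:
    """Ground-truth kinetic parameters for one simulated TU."""

    tu_id: str
    length: int
    velocity: float                 # body elongation velocity, bp/min
    initiation_frequency_I: float   # cell^-1 min^-1 (control)
    pause_position: int             # bp downstream of TSS
    pause_duration_d: float         # min (control)
    response_ratio_r: float
    pause_duration_d_inhibited: float
    initiation_frequency_I_inhibited: float
    first_exon_length: int
    first_intron_length: int

    def profile(self) -> VelocityProfile:
        return VelocityProfile.with_pause(
            self.velocity, self.pause_position, self.pause_duration_d
        )


@dataclass
class SimulationTruth:
    globals: GlobalSimParams
    tus: list[TruthTU]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.tus]).set_index("tu_id")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "globals": asdict(self.globals),
            "tus": [asdict(t) for t in self.tus],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            globals=GlobalSimParams(**payload["globals"]),
            tus=[TruthTU(**t) for t in payload["tus"]],
        )


# ---------------------------------------------------------------------------
# TT-seq simulation
# ---------------------------------------------------------------------------

def _fragment_weights(lengths: np.ndarray, params: GlobalSimParams) -> np.ndarray:
    return labeling_bias(lengths, params.labeling_probability, params.uracil_fraction) * \
        size_selection_weight(lengths, params.size_selection_midpoint, params.size_selection_scale)


def _response_window_end(truth: TruthTU, params: GlobalSimParams) -> float:
    """5' boundary below which labeled signal is depleted: the position of
    the fragment start of a polymerase released at treatment onset."""
    return min(
        truth.pause_position
        + truth.velocity * (params.treatment_duration - params.labeling_duration),
        float(truth.length),
    )


def expected_ttseq_coverage(
    truth: TruthTU,
    params: GlobalSimParams,
    condition: str = "control",
    ds: float = 0.005,
) -> np.ndarray:
    """Noiseless expected TT-seq coverage per base (units: kappa_true *
    labeled molecules per cell), by integrating over polymerase age."""
    L = truth.length
    if L < 200:
        raise ValueError("TU shorter than 200 bp")
    t_lab = params.labeling_duration
    if t_lab <= 0:
        return np.zeros(L)
    profile = truth.profile()
    s_max = profile.time_at(L) + t_lab
    ages = np.arange(ds / 2, s_max, ds)
    b = np.minimum(profile.position(ages), L)
    a = np.minimum(profile.position(np.maximum(ages - t_lab, 0.0)), L)
    w = _fragment_weights(b - a, params) * truth.initiation_frequency_I * ds
    if condition == "inhibited":
        r = truth.response_ratio_r
        if params.thinning == "sharp":
            x_resp = _response_window_end(truth, params)
            cov = _deposit_expected(a, b, w, L)
            cut = int(round(x_resp))
            cov[:cut] *= 1.0 - r
            return cov
        # kinetic: polymerases released within the final t* minutes thinned
        t_exit = profile.time_at(truth.pause_position + 1)
        affected = (ages >= t_exit) & (ages < t_exit + params.treatment_duration)
        w = np.where(affected, w * (1.0 - r), w)
        return _deposit_expected(a, b, w, L)
    elif condition != "control":
        raise ValueError("condition must be 'control' or 'inhibited'")
    return _deposit_expected(a, b, w, L)


def _deposit_expected(a: np.ndarray, b: np.ndarray, w: np.ndarray, L: int) -> np.ndarray:
    diff = np.zeros(L + 1)
    ai = np.clip(np.floor(a).astype(np.int64), 0, L)
    bi = np.clip(np.ceil(b).astype(np.int64), 0, L)
    ok = bi > ai
    np.add.at(diff, ai[ok], w[ok])
    np.add.at(diff, bi[ok], -w[ok])
    return np.cumsum(diff[:-1])


def sample_ttseq_coverage(
    truth: TruthTU,
    params: GlobalSimParams,
    condition: str,
    depth_factor: float,
    rng: np.random.Generator,
    rho: np.ndarray | None = None,
) -> np.ndarray:
    """One sampled TT-seq track (integer read coverage) for one TU.

    The labeled-RNA population of ~10^7 cells is effectively infinite, so
    sampling noise is read sampling alone: sequenced fragments (length
    ``sonication_mean_bp``) arrive as a Poisson process whose start-point
    intensity is the expected coverage profile scaled by kappa_true *
    depth_factor and divided by the fragment length.  Window sums then
    fluctuate with the number of overlapping reads, as in a real library.
    A precomputed expectation profile can be passed via ``rho`` to avoid
    recomputation across replicates.
    """
    L = truth.length
    if L < 200:
        raise ValueError("TU shorter than 200 bp")
    counts = np.zeros(L, dtype=np.int64)
    if params.labeling_duration <= 0:
        return counts
    if rho is None:
        rho = expected_ttseq_coverage(truth, params, condition)
    flen = int(params.sonication_mean_bp)
    lam = rho * (params.kappa_true * depth_factor)
    total = float(lam.sum())
    if total <= 0:
        return counts
    n = rng.poisson(total / flen)
    if n == 0:
        return counts
    cdf = np.cumsum(lam)
    starts = np.searchsorted(cdf, rng.uniform(0.0, total, n), side="right")
    ends = np.minimum(starts + flen, L)
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])


def simulate_ttseq_tu(
    truth: TruthTU,
    params: GlobalSimParams,
    condition: str = "control",
    seed: int | np.random.Generator = 0,
    depth_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected and sampled TT-seq coverage for one TU (TU-local, 5'->3')."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = expected_ttseq_coverage(truth, params, condition)
    sampled = sample_ttseq_coverage(truth, params, condition, depth_factor, rng)
    return expected, sampled


# ---------------------------------------------------------------------------
# mNET-seq simulation
# ---------------------------------------------------------------------------

def expected_mnet_occupancy(
    truth: TruthTU, params: GlobalSimParams, condition: str = "control"
) -> np.ndarray:
    """Expected polymerase occupancy per base: I / v(x) in the body plus a
    Gaussian pause peak carrying I*d (control) or I*d_inh (inhibited)
    polymerase equivalents."""
    L = truth.length
    x = np.arange(L)
    I = truth.initiation_frequency_I
    body = np.full(L, I / truth.velocity)
    if condition == "inhibited":
        reach = truth.pause_position + truth.velocity * params.treatment_duration
        body[x < reach] *= 1.0 - truth.response_ratio_r
        pause_mass = I * truth.pause_duration_d_inhibited
    elif condition == "control":
        pause_mass = I * truth.pause_duration_d
    else:
        raise ValueError("condition must be 'control' or 'inhibited'")
    sd = params.pause_read_sd
    kernel = np.exp(-0.5 * ((x - truth.pause_position) / sd) ** 2)
    kernel /= kernel.sum()
    return body + pause_mass * kernel


def simulate_mnet_tu(
    truth: TruthTU,
    params: GlobalSimParams,
    condition: str,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected occupancy and multinomially sampled counts at given depth."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = expected_mnet_occupancy(truth, params, condition)
    p = expected / expected.sum()
    counts = rng.multinomial(int(depth), p)
    return expected, counts


# ---------------------------------------------------------------------------
# spike-ins
# ---------------------------------------------------------------------------

@dataclass
class SpikeIn:
    name: str
    sequence: str
    labeled: bool

    @property
    def length(self) -> int:
        return len(self.sequence)

    def molar_mass(self, tau: float = 0.1) -> float:
        return molar_mass(self.sequence, self.labeled, tau)


def default_spikeins(seed: int = 7, n: int = 8, n_labeled: int = 4,
                     length_range: tuple[int, int] = (600, 2000),
                     uracil_fraction: float = 0.28) -> list[SpikeIn]:
    """Synthetic spike-in set (the experimental set is lab-specific): random
    sequences at the genomic uracil fraction, half labeled."""
    rng = np.random.default_rng(seed)
    other = (1 - uracil_fraction) / 3
    spikes = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list("ACGU"), size=L,
                                 p=[other, other, other, uracil_fraction]))
        spikes.append(SpikeIn(name=f"spike{i + 1}", sequence=seq, labeled=i < n_labeled))
    return spikes


def simulate_spikeins(
    spikeins: Sequence[SpikeIn],
    kappa: float,
    c_true: float,
    depth_factors: Mapping[str, float],
    seed: int | np.random.Generator = 0,
    mass_g: float = 25e-9,
    n_cells: float = 3.27e7,
    background: float = 0.005,
) -> CountTable:
    """Spike-in count table across samples in transcribed-base units.

    Labeled spike-ins yield sense signal kappa * sigma_j * N_i * L_i (N_i
    from the molar-mass model); unlabeled ones only a small purification
    background.  Antisense signal arises at rate ``c_true``.
    """
    if not any(s.labeled for s in spikeins):
        raise ValueError("need at least one labeled spike-in")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [s.name for s in spikeins]
    sense = pd.DataFrame(index=names, columns=list(depth_factors), dtype=float)
    anti = sense.copy()
    for sample, sigma in depth_factors.items():
        means = []
        for s in spikeins:
            N = spikein_molecules_per_cell(mass_g, n_cells, s.molar_mass())
            mean = kappa * sigma * N * s.length
            means.append(mean if s.labeled else background * mean)
        means = np.asarray(means)
        sense[sample] = rng.poisson(means).astype(float)
        anti[sample] = rng.poisson(c_true * means).astype(float)
    return CountTable(sense=sense, antisense=anti)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A complete in-memory synthetic experiment."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    genome: dict[str, str]
    coverages: list[StrandedCoverage]
    spikeins: list[SpikeIn]
    spike_counts: CountTable
    truth: SimulationTruth

    @property
    def params(self) -> GlobalSimParams:
        return self.truth.globals

    def coverage(self, assay: str, condition: str, replicate: int) -> StrandedCoverage:
        for cov in self.coverages:
            if (cov.assay, cov.condition, cov.replicate) == (assay, condition, replicate):
                return cov
        raise KeyError((assay, condition, replicate))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.genes, outdir / "annotation.gtf")
        write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")
        for cov in self.coverages:
            write_bedgraph(cov.plus, outdir / f"{cov.sample_id}.plus.bedgraph")
            write_bedgraph(cov.minus, outdir / f"{cov.sample_id}.minus.bedgraph")
        with open(outdir / "spikeins.fasta", "w") as fh:
            for s in self.spikeins:
                fh.write(f">{s.name} labeled={'true' if s.labeled else 'false'}\n{s.sequence}\n")
        self.spike_counts.to_tsv(outdir / "spike_counts.tsv")
        self.truth.to_json(outdir / "truth.json")
        with open(outdir / "genome.fasta", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i: i + 80] + "\n")
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample_id\tassay\tcondition\treplicate\n")
            for cov in self.coverages:
                fh.write(f"{cov.sample_id}\t{cov.assay}\t{cov.condition}\t{cov.replicate}\n")


def sample_truth(
    rng: np.random.Generator,
    n_tus: int,
    params: GlobalSimParams,
    length_range: tuple[int, int] = (10_000, 200_000),
    mean_initiation: float = 2.7,
    sigma_log_initiation: float = 1.2,
    median_velocity: float = 2400.0,
    sigma_log_velocity: float = 0.49,
    pause_mode: float = 84.0,
    pause_spread: float = 25.0,
    limit_fraction_range: tuple[float, float] = (0.08, 0.9),
    steric_constraint: bool = True,
    nonresponder_fraction: float = 0.07,
    inhibition_dwell_floor: float = 0.125,
) -> list[dict]:
    """Draw per-TU kinetic parameters.

    Initiation frequencies are log-normal with the cohort mean pinned at
    ``mean_initiation``; pause durations are drawn as a log-uniform fraction
    of the steric ceiling (pause_window/steric_distance)/I so the (I, d)
    cloud lies along — and, with the constraint on, below — the
    pause-initiation limit, anti-correlated as observed for human genes.
    With ``steric_constraint`` fractions above the admissible range are
    resampled (logged); switching it off admits impossible combinations.
    """
    lo, hi = length_range
    out = []
    u_lo, u_hi = limit_fraction_range
    for i in range(n_tus):
        L = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        v = float(rng.lognormal(np.log(median_velocity), sigma_log_velocity))
        v = max(v, 300.0)
        I = float(rng.lognormal(np.log(mean_initiation) - sigma_log_initiation**2 / 2,
                                sigma_log_initiation))
        u = float(np.exp(rng.uniform(np.log(u_lo), np.log(1.8))))
        while steric_constraint and u > u_hi:
            logger.debug("TU %d: limit fraction %.2f infeasible, resampled", i, u)
            u = float(np.exp(rng.uniform(np.log(u_lo), np.log(1.8))))
        d = 4.0 * u / I  # (200 bp / 50 bp) / I is the steric ceiling on d
        if rng.random() < nonresponder_fraction:
            r = float(rng.uniform(0.0, 0.04))
        else:
            r = float(rng.beta(2.9, 2.1))
        d_inh = min(d / max(1.0 - r, inhibition_dwell_floor),
                    params.steric_occupancy_cap / I)
        d_inh = max(d_inh, d)
        out.append(dict(length=L, velocity=v, initiation=I, pause_duration=d,
                        response_ratio=r, d_inhibited=d_inh,
                        I_inhibited=I * (1.0 - r)))
    return out


def _gene_structure(
    rng: np.random.Generator,
    length: int,
    velocity: float,
    median_velocity: float,
    sigma_log_velocity: float,
    intron_velocity_association: bool,
) -> list[tuple[int, int]]:
    """TU-local exon intervals: first exon, a first intron whose length is
    (optionally) rank-associated with elongation velocity, then alternating
    exons/introns to the TU end."""
    first_exon = int(rng.integers(250, 601))
    z = (np.log(velocity) - np.log(median_velocity)) / sigma_log_velocity
    mu = np.log(3000.0) + (0.8 * z if intron_velocity_association else 0.0)
    first_intron = int(np.clip(np.exp(mu + rng.normal(0, 0.6)), 500, max(length // 3, 600)))
    exons = [(0, first_exon)]
    pos = first_exon + first_intron
    while pos < length - 200:
        ex = int(np.clip(rng.lognormal(np.log(400.0), 0.5), 100, 3000))
        end = min(pos + ex, length)
        exons.append((pos, end))
        pos = end + int(np.clip(rng.lognormal(np.log(1500.0), 0.8), 200, 20_000))
    if exons[-1][1] < length:
        if length - exons[-1][1] < 300:
            exons[-1] = (exons[-1][0], length)
        else:
            exons.append((length - 200, length))
    return exons


def generate_cohort(
    n_tus: int,
    seed: int,
    params: GlobalSimParams | None = None,
    length_range: tuple[int, int] = (10_000, 200_000),
    steric_constraint: bool = True,
    intron_velocity_association: bool = True,
    two_isoform_fraction: float = 0.0,
    write_dir: str | Path | None = None,
    **truth_kwargs,
) -> Cohort:
    """Generate a full synthetic cohort, reproducible from ``seed``.

    Writes GTF, bedGraph pairs (2 assays x 2 conditions x 2 replicates),
    spike-in FASTA and counts, genome FASTA and truth JSON when
    ``write_dir`` is given.
    """
    if n_tus < 1:
        raise ValueError("need at least one TU")
    rng = np.random.default_rng(seed)
    params = params or GlobalSimParams()
    depth = dict(_DEFAULT_DEPTHS)
    depth.update(params.depth_factors)

    med_v = truth_kwargs.get("median_velocity", 2400.0)
    sig_v = truth_kwargs.get("sigma_log_velocity", 0.49)
    raw = sample_truth(rng, n_tus, params, length_range=length_range,
                       steric_constraint=steric_constraint, **truth_kwargs)

    # --- placement: pack TUs onto chromosomes with gaps, alternating strand
    gap = 3000
    chrom_cap = 1_200_000
    genes: list[GeneModel] = []
    truth_tus: list[TruthTU] = []
    placements: list[tuple[str, int, str]] = []  # chrom, start, strand
    chrom_sizes: dict[str, int] = {}
    chrom_idx, cursor = 1, gap
    for i, tr in enumerate(raw):
        L = tr["length"]
        chrom = f"chr{chrom_idx}"
        if cursor + L + gap > chrom_cap and cursor > gap:
            chrom_sizes[chrom] = cursor
            chrom_idx += 1
            cursor = gap
            chrom = f"chr{chrom_idx}"
        start = cursor
        cursor += L + gap
        strand = "+" if rng.random() < 0.5 else "-"
        tu_id = f"TU{i + 1:04d}"

        local_exons = _gene_structure(rng, L, tr["velocity"], med_v, sig_v,
                                      intron_velocity_association)
        first_exon_len = local_exons[0][1]
        pause = int(np.clip(rng.normal(84.0, 25.0), 20, first_exon_len - 40))
        if strand == "+":
            genomic = tuple((start + s, start + e) for s, e in local_exons)
        else:
            genomic = tuple(sorted((start + L - e, start + L - s) for s, e in local_exons))
        isoforms = [genomic]
        if rng.random() < two_isoform_fraction and len(genomic) > 2:
            k = int(rng.integers(1, len(genomic)))
            isoforms.append(tuple(iv for j, iv in enumerate(genomic) if j != k))
        genes.append(GeneModel(tu_id, chrom, strand, tuple(isoforms)))
        placements.append((chrom, start, strand))
        truth_tus.append(TruthTU(
            tu_id=tu_id, length=L, velocity=tr["velocity"],
            initiation_frequency_I=tr["initiation"], pause_position=pause,
            pause_duration_d=tr["pause_duration"], response_ratio_r=tr["response_ratio"],
            pause_duration_d_inhibited=tr["d_inhibited"],
            initiation_frequency_I_inhibited=tr["I_inhibited"],
            first_exon_length=first_exon_len,
            first_intron_length=local_exons[1][0] - local_exons[0][1] if len(local_exons) > 1 else 0,
        ))
    chrom_sizes[f"chr{chrom_idx}"] = cursor

    # --- genome with a planted C at each pause site (RNA 3'-end base)
    genome_codes = {c: rng.integers(0, 4, size=n, dtype=np.uint8) for c, n in chrom_sizes.items()}
    for tu, (chrom, start, strand) in zip(truth_tus, placements):
        if strand == "+":
            genome_codes[chrom][start + tu.pause_position] = 1  # C
        else:
            genome_codes[chrom][start + tu.length - 1 - tu.pause_position] = 2  # G -> C on sense
    genome = {c: _BASES[v].tobytes().decode() for c, v in genome_codes.items()}

    # --- coverage tracks
    tracks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for sample_id, _, _ in TT_SAMPLES + MNET_SAMPLES:
        tracks[sample_id] = {
            # int16 keeps 16 genome-wide tracks affordable; expected coverage
            # stays O(10^3) (kappa*sigma*I*t_lab), well below the dtype limit
            "+": {c: np.zeros(n, dtype=np.int16) for c, n in chrom_sizes.items()},
            "-": {c: np.zeros(n, dtype=np.int16) for c, n in chrom_sizes.items()},
        }

    def deposit(sample_id, chrom, start, L, strand, local: np.ndarray, sense: bool = True):
        track_strand = strand if sense else ("-" if strand == "+" else "+")
        arr = tracks[sample_id][track_strand][chrom]
        if strand == "+":
            arr[start: start + L] += local
        else:
            arr[start: start + L] += local[::-1]

    c_true = params.antisense_bleed
    for tu, (chrom, start, strand) in zip(truth_tus, placements):
        rho = {cond: expected_ttseq_coverage(tu, params, cond)
               for cond in ("control", "inhibited")}
        for sample_id, condition, _ in TT_SAMPLES:
            local = sample_ttseq_coverage(
                tu, params, condition, depth[sample_id], rng, rho=rho[condition])
            deposit(sample_id, chrom, start, tu.length, strand, local)
            anti = sample_ttseq_coverage(
                tu, params, condition, depth[sample_id] * c_true, rng, rho=rho[condition])
            deposit(sample_id, chrom, start, tu.length, strand, anti, sense=False)
        for sample_id, condition, _ in MNET_SAMPLES:
            lam = params.mnet_depth * depth[sample_id] * expected_mnet_occupancy(tu, params, condition)
            local = rng.poisson(lam)
            deposit(sample_id, chrom, start, tu.length, strand, local)
            deposit(sample_id, chrom, start, tu.length, strand,
                    rng.poisson(c_true * lam), sense=False)

    coverages = [
        StrandedCoverage(
            sample_id=sid, assay="ttseq" if sid.startswith("tt") else "mnet",
            condition=cond, replicate=rep,
            plus=tracks[sid]["+"], minus=tracks[sid]["-"],
        )
        for sid, cond, rep in TT_SAMPLES + MNET_SAMPLES
    ]

    spikeins = default_spikeins(seed=int(rng.integers(0, 2**31)))
    spike_counts = simulate_spikeins(
        spikeins, params.kappa_true, c_true,
        {sid: depth[sid] for sid, _, _ in TT_SAMPLES + MNET_SAMPLES},
        rng, params.spike_mass_g, params.spike_cells,
    )

    cohort = Cohort(
        genes=genes, chrom_sizes=chrom_sizes, genome=genome, coverages=coverages,
        spikeins=spikeins, spike_counts=spike_counts,
        truth=SimulationTruth(globals=params, tus=truth_tus),
    )
    if write_dir is not None:
        cohort.write(write_dir)
    return cohort
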