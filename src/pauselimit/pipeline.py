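"""End-to-end orchestration: from annotation + coverage + spike-ins to
per-TU kinetic estimates, metagene profiles and summary reports.

Stage order (each consuming the previous stage's normalized quantities):

1. TU construction and RPK expression filtering (corrected control TT-seq);
2. per-sample normalization: antisense bias c from spike-ins, TT-seq size
   factors on long TUs trimmed 50 kbp per side, mNET-seq size factors on
   non-responder TUs, spike-in conversion factor kappa;
3. response ratios on [200 bp, 10 kbp), the robust common velocity fit, and
   both gene-wise velocity estimators;
4. pause-site calling from control mNET-seq, initiation frequencies over
   non-first constitutive exons, pause durations d and d_hat, and the
   pause-initiation-limit margin per TU and condition.

The pipeline output is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .annotation_io import (
    CountTable,
    GeneModel,
    StrandedCoverage,
    TranscriptionUnit,
    build_tus,
    expression_filter,
    load_coverage,
    read_chrom_sizes,
    read_gtf,
    tu_local_view,
)
from .normalization import (
    antisense_bias_ratio,
    conversion_factor,
    corrected_counts,
    mnet_size_factors,
    size_factors,
    spikein_molecules_per_cell,
)
from .pausing_kinetics import (
    LimitConfig,
    detect_pause_site,
    dhat_display_factor,
    initiation_frequency,
    limit_check,
    pause_duration,
    pause_duration_noI,
    pause_scale_factor,
    pause_window_bounds,
)
from .response_kinetics import (
    fit_common_velocity,
    gene_velocity,
    response_ratio,
    response_window_length,
    transcribed_bases,
)
from .sequence_features import PWM_FLANK, pause_pwm
from .synthetic_data import Cohort, SpikeIn

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and experiment containers
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All pipeline constants (times in minutes, lengths in bp)."""

    t_lab: float = 5.0
    t_star: float = 15.0
    rpk_threshold: float = 100.0
    fragment_length: float = 200.0
    min_tu_length: int = 10_000
    response_window: tuple[int, int] = (200, 10_000)
    sizefactor_min_length: int = 125_000
    sizefactor_trim: int = 50_000
    common_fit_range: tuple[int, int] = (25_000, 200_000)
    velocity_min_length: int = 35_000
    three_prime_trim: int = 5_000
    r_min_velocity: float = 0.25
    nonresponder_threshold: float = 0.05
    pause_peak_fold: float = 5.0
    pause_window_halfwidth: float = 100.0
    steric_distance: float = 50.0
    spike_mass_g: float = 25e-9
    spike_cells: float = 3.27e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_star <= self.t_lab:
            raise ValueError("treatment duration must exceed labeling duration")

    @property
    def limit(self) -> LimitConfig:
        return LimitConfig(
            pause_window_halfwidth=self.pause_window_halfwidth,
            steric_distance=self.steric_distance,
            pause_peak_fold=self.pause_peak_fold,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class Experiment:
    """Inputs to the pipeline; :class:`~pauselimit.synthetic_data.Cohort`
    satisfies the same interface with ground truth attached."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    coverages: list[StrandedCoverage]
    spike_counts: CountTable
    spikeins: list[SpikeIn]
    genome: dict[str, str] | None = None
    truth: object | None = None


def load_experiment(indir: str | Path) -> Experiment:
    """Load an experiment directory (as written by ``Cohort.write`` or
    assembled by hand: annotation.gtf, chrom.sizes, samples.tsv,
    <sample>.plus/.minus.bedgraph, spikeins.fasta, spike_counts.tsv and
    optionally genome.fasta, truth.json)."""
    from Bio import SeqIO

    indir = Path(indir)
    genes = read_gtf(indir / "annotation.gtf")
    chrom_sizes = read_chrom_sizes(indir / "chrom.sizes")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    coverages = [
        load_coverage(
            indir / f"{row.sample_id}.plus.bedgraph",
            indir / f"{row.sample_id}.minus.bedgraph",
            chrom_sizes,
            sample_id=row.sample_id, assay=row.assay,
            condition=row.condition, replicate=int(row.replicate),
        )
        for row in samples.itertuples()
    ]
    spikeins = []
    for rec in SeqIO.parse(str(indir / "spikeins.fasta"), "fasta"):
        labeled = "labeled=true" in rec.description.lower()
        spikeins.append(SpikeIn(name=rec.id, sequence=str(rec.seq), labeled=labeled))
    spike_counts = CountTable.from_tsv(indir / "spike_counts.tsv")
    genome = None
    if (indir / "genome.fasta").exists():
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(indir / "genome.fasta"), "fasta")}
    truth = None
    if (indir / "truth.json").exists():
        from .synthetic_data import SimulationTruth

        truth = SimulationTruth.from_json(indir / "truth.json")
    return Experiment(
        genes=genes, chrom_sizes=chrom_sizes, coverages=coverages,
        spike_counts=spike_counts, spikeins=spikeins, genome=genome, truth=truth,
    )


@dataclass
class PipelineResult:
    kinetics: pd.DataFrame
    normalization: pd.DataFrame
    summary: dict
    config: PipelineConfig
    pwm: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# pauselimit {__version__} config_hash={self.config.hash()}\n"
        for name, df in (("kinetics", self.kinetics), ("normalization", self.normalization)):
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t")
        if self.pwm is not None:
            with open(outdir / "pause_pwm.tsv", "w") as fh:
                fh.write(header)
                self.pwm.to_csv(fh, sep="\t")
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=1, default=float))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _by(coverages: Sequence[StrandedCoverage], assay: str, condition: str) -> list[StrandedCoverage]:
    return sorted(
        (c for c in coverages if c.assay == assay and c.condition == condition),
        key=lambda c: c.replicate,
    )


def run_pipeline(exp: Experiment | Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full analysis; see module docstring for stage order."""
    config = config or PipelineConfig()
    dt = config.t_star - config.t_lab

    tus_all = build_tus(exp.genes)
    tt_ctrl = _by(exp.coverages, "ttseq", "control")
    tt_inh = _by(exp.coverages, "ttseq", "inhibited")
    mnet_ctrl = _by(exp.coverages, "mnet", "control")
    mnet_inh = _by(exp.coverages, "mnet", "inhibited")
    if not tt_ctrl or not tt_inh:
        raise RuntimeError("stage normalize: need TT-seq tracks for both conditions")

    # --- antisense bias from spike-ins
    c_by_sample = antisense_bias_ratio(exp.spike_counts)

    def c_of(cov: StrandedCoverage) -> float:
        return float(c_by_sample.get(cov.sample_id, 0.0))

    # --- expression filter on corrected control TT-seq read counts
    rows = {}
    for tu in tus_all:
        vals = []
        for cov in tt_ctrl:
            sense = tu_local_view(cov, tu, (0, tu.length)).sum() / config.fragment_length
            anti = tu_local_view(cov, tu, (0, tu.length), antisense=True).sum() / config.fragment_length
            vals.append(corrected_counts(sense, anti, c_of(cov)))
        rows[tu.tu_id] = vals
    counts_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.sample_id for c in tt_ctrl]
    )
    expressed = expression_filter(tus_all, counts_df, config.rpk_threshold)
    if not expressed:
        raise RuntimeError("stage filter: no expressed TU passes the RPK threshold")

    def tb_one(cov, tu, window, sigma=1.0, intervals=None):
        return transcribed_bases(cov, tu, window, c=c_of(cov), sigma=sigma, intervals=intervals)

    # --- TT-seq size factors on long TUs, 50 kbp trimmed per side
    tt_all = tt_ctrl + tt_inh
    long_tus = [t for t in expressed if t.length > config.sizefactor_min_length]
    if not long_tus:
        raise RuntimeError(
            f"stage normalize: no TU exceeds {config.sizefactor_min_length} bp for size factors"
        )
    sf_tb = pd.DataFrame(
        {
            cov.sample_id: [
                tb_one(cov, t, (config.sizefactor_trim, t.length - config.sizefactor_trim))
                for t in long_tus
            ]
            for cov in tt_all
        },
        index=[t.tu_id for t in long_tus],
    )
    sigma_tt = size_factors(sf_tb)

    def sig(cov) -> float:
        return float(sigma_tt.get(cov.sample_id, 1.0))

    def cond_tb(tu, window, covs, sigmas=None, intervals=None):
        vals = [
            tb_one(cov, tu, window, sigma=(sigmas[cov.sample_id] if sigmas is not None else sig(cov)),
                   intervals=intervals)
            for cov in covs
        ]
        return float(np.mean(vals))

    # --- response ratios (window [200 bp, 10 kbp)); multi-TSS TUs are kept
    #     here so they can serve the mNET normalization, as flagged
    r_all: dict[str, float] = {}
    for tu in expressed:
        if tu.length <= config.min_tu_length:
            continue
        tbc = cond_tb(tu, config.response_window, tt_ctrl)
        tbi = cond_tb(tu, config.response_window, tt_inh)
        if tbc <= 0:
            logger.warning("TU %s dropped: zero control signal in response window", tu.tu_id)
            continue
        r_all[tu.tu_id] = response_ratio(tbc, tbi)
    analysis_tus = [
        t for t in expressed
        if t.tu_id in r_all and t.unique_tss and t.length > config.min_tu_length
    ]
    if not analysis_tus:
        raise RuntimeError("stage response: no TU eligible for response analysis")

    # --- mNET-seq size factors on non-responders
    sigma_mnet = None
    if mnet_ctrl or mnet_inh:
        mnet_all = mnet_ctrl + mnet_inh
        cand = [t for t in expressed if t.tu_id in r_all]
        mnet_tb = pd.DataFrame(
            {cov.sample_id: [tb_one(cov, t, (0, t.length)) for t in cand] for cov in mnet_all},
            index=[t.tu_id for t in cand],
        )
        r_series = pd.Series(r_all)
        try:
            sigma_mnet = mnet_size_factors(mnet_tb, r_series, config.nonresponder_threshold)
        except ValueError as err:
            logger.warning("mNET size factors fall back to all TUs: %s", err)
            sigma_mnet = size_factors(mnet_tb)

    # --- spike-in conversion factor kappa (labeled TT-seq samples)
    spike_meta = pd.DataFrame(
        {
            "length": [s.length for s in exp.spikeins],
            "labeled": [s.labeled for s in exp.spikeins],
            "N": [
                spikein_molecules_per_cell(config.spike_mass_g, config.spike_cells, s.molar_mass())
                for s in exp.spikeins
            ],
        },
        index=[s.name for s in exp.spikeins],
    )
    spike_tb = pd.DataFrame(index=exp.spike_counts.sense.index)
    for cov in tt_all:
        s = exp.spike_counts.sense[cov.sample_id]
        a = exp.spike_counts.antisense[cov.sample_id]
        spike_tb[cov.sample_id] = corrected_counts(s.to_numpy(), a.to_numpy(), c_of(cov)) / sig(cov)
    kappa = conversion_factor(spike_tb, spike_meta["length"], spike_meta["N"], spike_meta["labeled"])

    # --- per-TU kinetics
    records: dict[str, dict] = {}
    for tu in analysis_tus:
        L = tu.length
        rec: dict = dict(
            length=L, strand=tu.strand, response_ratio=r_all[tu.tu_id],
            tb_control=np.nan, tb_inhibited=np.nan,
            velocity_kbp_min=np.nan, vhat_kbp_min=np.nan, response_window_bp=np.nan,
        )
        body = (config.response_window[0], max(L - config.three_prime_trim,
                                               config.response_window[0] + 1))
        rec["tb_control"] = cond_tb(tu, body, tt_ctrl)
        rec["tb_inhibited"] = cond_tb(tu, body, tt_inh)
        if L > config.velocity_min_length:
            v = gene_velocity(
                rec["tb_control"], rec["tb_inhibited"], rec["response_ratio"], L,
                config.t_star, config.t_lab, config.r_min_velocity,
            )
            rec["velocity_kbp_min"] = np.nan if v is None else v
            if rec["response_ratio"] > config.r_min_velocity:
                diff = np.zeros(L)
                a, b = body
                for cov in tt_ctrl:
                    sense = tu_local_view(cov, tu, (a, b))
                    anti = tu_local_view(cov, tu, (a, b), antisense=True)
                    diff[a:b] += corrected_counts(sense, anti, c_of(cov)) / sig(cov) / len(tt_ctrl)
                for cov in tt_inh:
                    sense = tu_local_view(cov, tu, (a, b))
                    anti = tu_local_view(cov, tu, (a, b), antisense=True)
                    diff[a:b] -= corrected_counts(sense, anti, c_of(cov)) / sig(cov) / len(tt_inh)
                rw = response_window_length(diff, L, config.t_star, config.t_lab)
                if rw is not None:
                    rec["response_window_bp"] = rw[0]
                    rec["vhat_kbp_min"] = rw[1] / 1000.0
        records[tu.tu_id] = rec

    kin = pd.DataFrame.from_dict(records, orient="index").rename_axis("tu_id")

    # --- robust common velocity (TUs 25-200 kbp)
    fit_mask = kin["length"].between(*config.common_fit_range) & (kin["tb_control"] > 0)
    fit = None
    if fit_mask.sum() >= 10:
        sub = kin[fit_mask]
        fit = fit_common_velocity(
            (sub["tb_inhibited"] / sub["tb_control"]).to_numpy(),
            sub["response_ratio"].to_numpy(),
            sub["length"].to_numpy(dtype=float),
            config.t_star, config.t_lab,
        )

    # --- mNET-derived pausing kinetics per condition
    pwm = None
    if sigma_mnet is not None:
        tu_by_id = {t.tu_id: t for t in analysis_tus}

        def mnet_track(tu, covs):
            acc = np.zeros(tu.length)
            for cov in covs:
                sense = tu_local_view(cov, tu, (0, tu.length))
                anti = tu_local_view(cov, tu, (0, tu.length), antisense=True)
                acc += corrected_counts(sense, anti, c_of(cov)) / float(sigma_mnet[cov.sample_id])
            return acc / len(covs)

        for col in ("pause_site", "pause_strength", "initiation_control",
                    "initiation_inhibited", "mnet_pause_sum_control",
                    "mnet_rw_sum_control", "mnet_pause_sum_inhibited",
                    "mnet_rw_sum_inhibited", "mnet_rw_sum_dhat",
                    "pause_duration_control", "pause_duration_inhibited",
                    "dhat_raw", "dhat", "limit_margin"):
            kin[col] = np.nan
        kin["limit_violation"] = pd.Series(dtype=object)

        tracks_c: dict[str, np.ndarray] = {}
        tracks_i: dict[str, np.ndarray] = {}
        for tu in analysis_tus:
            tid = tu.tu_id
            track_c = mnet_track(tu, mnet_ctrl)
            track_i = mnet_track(tu, mnet_inh) if mnet_inh else None
            tracks_c[tid], tracks_i[tid] = track_c, track_i
            fe = tu.first_exon_end_offset() - 5
            if fe >= 20:
                hit = detect_pause_site(track_c[:fe], config.pause_peak_fold)
                if hit is not None:
                    kin.loc[tid, "pause_site"] = hit[0]
                    kin.loc[tid, "pause_strength"] = hit[1]
            exonic = tu.local_intervals(tu.nonfirst_constitutive_exons)
            l_ex = sum(e - s for s, e in exonic)
            if l_ex > 0:
                tb_ex_c = cond_tb(tu, (0, tu.length), tt_ctrl, intervals=exonic)
                tb_ex_i = cond_tb(tu, (0, tu.length), tt_inh, intervals=exonic)
                kin.loc[tid, "initiation_control"] = initiation_frequency(
                    tb_ex_c, kappa, config.t_lab, l_ex)
                kin.loc[tid, "initiation_inhibited"] = initiation_frequency(
                    tb_ex_i, kappa, config.t_lab, l_ex)
            else:
                logger.warning("TU %s skipped for I: no non-first constitutive exons", tid)
            if not np.isnan(kin.loc[tid, "pause_site"]):
                lo, hi = pause_window_bounds(int(kin.loc[tid, "pause_site"]),
                                             config.pause_window_halfwidth)
                hi = min(hi, tu.length)
                kin.loc[tid, "mnet_pause_sum_control"] = track_c[lo:hi].sum()
                if track_i is not None:
                    kin.loc[tid, "mnet_pause_sum_inhibited"] = track_i[lo:hi].sum()
            v = kin.loc[tid, "velocity_kbp_min"]
            if np.isfinite(v):
                rw_end = int(min(v * 1000.0 * dt, tu.length - config.three_prime_trim))
                if rw_end > config.response_window[0]:
                    kin.loc[tid, "mnet_rw_sum_control"] = track_c[config.response_window[0]: rw_end].sum()
                    if track_i is not None:
                        kin.loc[tid, "mnet_rw_sum_inhibited"] = track_i[config.response_window[0]: rw_end].sum()
            l_rw = kin.loc[tid, "response_window_bp"]
            if np.isfinite(l_rw) and l_rw > config.response_window[0]:
                kin.loc[tid, "mnet_rw_sum_dhat"] = track_c[config.response_window[0]: int(l_rw)].sum()

        scale_c = scale_i = None
        try:
            scale_c = pause_scale_factor(
                kin["initiation_control"].to_numpy(), kin["mnet_rw_sum_control"].to_numpy(),
                config.t_star, config.t_lab)
            if mnet_inh:
                scale_i = pause_scale_factor(
                    kin["initiation_inhibited"].to_numpy(), kin["mnet_rw_sum_inhibited"].to_numpy(),
                    config.t_star, config.t_lab)
        except ValueError as err:
            logger.warning("pause scale factor unavailable: %s", err)

        for tid in kin.index:
            I_c = kin.loc[tid, "initiation_control"]
            psum_c = kin.loc[tid, "mnet_pause_sum_control"]
            if scale_c is not None and np.isfinite(I_c) and I_c > 0 and np.isfinite(psum_c):
                kin.loc[tid, "pause_duration_control"] = pause_duration(psum_c, I_c, scale_c)
            I_i = kin.loc[tid, "initiation_inhibited"]
            psum_i = kin.loc[tid, "mnet_pause_sum_inhibited"]
            if scale_i is not None and np.isfinite(I_i) and I_i > 0 and np.isfinite(psum_i):
                kin.loc[tid, "pause_duration_inhibited"] = pause_duration(psum_i, I_i, scale_i)
            rw_dhat = kin.loc[tid, "mnet_rw_sum_dhat"]
            l_rw = kin.loc[tid, "response_window_bp"]
            vhat = kin.loc[tid, "vhat_kbp_min"]
            if np.isfinite(rw_dhat) and np.isfinite(l_rw) and np.isfinite(vhat) and np.isfinite(psum_c):
                dh = pause_duration_noI(psum_c, rw_dhat, l_rw, vhat * 1000.0)
                if dh is not None:
                    kin.loc[tid, "dhat_raw"] = dh

        factor = dhat_display_factor(
            kin["pause_duration_control"].to_numpy(), kin["dhat_raw"].to_numpy())
        if np.isfinite(factor):
            kin["dhat"] = kin["dhat_raw"] * factor
        for tid in kin.index:
            d = kin.loc[tid, "pause_duration_control"]
            I_c = kin.loc[tid, "initiation_control"]
            if np.isfinite(d) and d > 0 and np.isfinite(I_c) and I_c > 0:
                margin, viol = limit_check(d, I_c, config.limit)
                kin.loc[tid, "limit_margin"] = margin
                kin.loc[tid, "limit_violation"] = bool(viol)

        if exp.genome is not None:
            seqs = []
            for tid in kin.index[kin["pause_site"].notna()]:
                tu = tu_by_id[tid]
                seq = pause_site_sequence(exp.genome, tu, int(kin.loc[tid, "pause_site"]))
                if seq is not None:
                    seqs.append(seq)
            if seqs:
                pwm = pause_pwm(seqs)

    norm = pd.DataFrame({"antisense_bias_c": c_by_sample})
    norm["size_factor_sigma"] = sigma_tt.reindex(norm.index)
    if sigma_mnet is not None:
        norm["size_factor_sigma"] = norm["size_factor_sigma"].fillna(
            sigma_mnet.reindex(norm.index))
    norm["conversion_kappa"] = np.nan
    for cov in tt_all:
        norm.loc[cov.sample_id, "conversion_kappa"] = kappa
    norm = norm.rename_axis("sample_id")

    summary = _summarize(kin, fit, kappa, exp, config)
    return PipelineResult(kinetics=kin, normalization=norm, summary=summary, config=config, pwm=pwm)


def pause_site_sequence(genome: Mapping[str, str], tu: TranscriptionUnit, m_star: int) -> str | None:
    """Sense-strand sequence +-PWM_FLANK around a TU-local pause site."""
    if tu.strand == "+":
        g = tu.tss + m_star
        lo, hi = g - PWM_FLANK, g + PWM_FLANK + 1
        if lo < 0 or hi > len(genome[tu.chrom]):
            return None
        return genome[tu.chrom][lo:hi].upper()
    g = tu.tss - m_star
    lo, hi = g - PWM_FLANK, g + PWM_FLANK + 1
    if lo < 0 or hi > len(genome[tu.chrom]):
        return None
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return genome[tu.chrom][lo:hi].translate(comp)[::-1].upper()


def _summarize(kin: pd.DataFrame, fit, kappa: float, exp, config: PipelineConfig) -> dict:
    def med(col):
        if col not in kin:
            return None
        v = kin[col].dropna()
        return float(v.median()) if len(v) else None

    summary: dict = {
        "n_tus_analyzed": int(len(kin)),
        "kappa": float(kappa),
        "median_response_ratio": med("response_ratio"),
        "median_velocity_kbp_min": med("velocity_kbp_min"),
        "mean_velocity_kbp_min": (
            float(kin["velocity_kbp_min"].dropna().mean())
            if "velocity_kbp_min" in kin and kin["velocity_kbp_min"].notna().any() else None
        ),
        "median_vhat_kbp_min": med("vhat_kbp_min"),
        "common_velocity_kbp_min": None if fit is None else fit.v_common / 1000.0,
        "median_pause_duration_min": med("pause_duration_control"),
        "median_initiation_per_cell_min": med("initiation_control"),
        "mean_initiation_per_cell_min": (
            float(kin["initiation_control"].dropna().mean())
            if "initiation_control" in kin and kin["initiation_control"].notna().any() else None
        ),
        "config_hash": config.hash(),
        "version": __version__,
    }
    if "limit_violation" in kin:
        flags = kin["limit_violation"].dropna()
        summary["limit_violation_fraction"] = (
            float(flags.astype(bool).mean()) if len(flags) else None
        )
    if "pause_site" in kin:
        ps = kin["pause_site"].dropna()
        summary["n_pause_sites"] = int(len(ps))
        summary["median_pause_site_bp"] = float(ps.median()) if len(ps) else None
    if exp.truth is not None:
        summary["recovery"] = truth_recovery(kin, exp.truth.frame())
    return summary


def truth_recovery(kin: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Spearman correlations and median relative errors of the kinetic
    estimates against simulation ground truth."""
    joined = kin.join(truth, how="inner", rsuffix="_true")
    pairs = {
        "I": ("initiation_control", "initiation_frequency_I"),
        "d": ("pause_duration_control", "pause_duration_d"),
        "v": ("velocity_kbp_min", "velocity"),
        "vhat": ("vhat_kbp_min", "velocity"),
        "r": ("response_ratio", "response_ratio_r"),
    }
    out: dict = {}
    for key, (est_col, true_col) in pairs.items():
        if est_col not in joined:
            continue
        est = joined[est_col].to_numpy(dtype=float)
        tru = joined[true_col].to_numpy(dtype=float)
        if key in ("v", "vhat"):
            tru = tru / 1000.0
        ok = np.isfinite(est) & np.isfinite(tru) & (tru > 0)
        if ok.sum() < 3:
            continue
        rho = stats.spearmanr(est[ok], tru[ok]).statistic
        out[f"spearman_{key}"] = float(rho)
        out[f"median_rel_err_{key}"] = float(np.median(np.abs(est[ok] - tru[ok]) / tru[ok]))
        out[f"n_{key}"] = int(ok.sum())
    return out


# ---------------------------------------------------------------------------
# metagene aggregation and descriptive correlates
# ---------------------------------------------------------------------------

def metagene(
    coverages: Sequence[StrandedCoverage],
    tus: Sequence[TranscriptionUnit],
    anchor: str = "tss",
    flank: tuple[int, int] = (0, 2000),
    anchors: Mapping[str, int] | None = None,
    rescale_bins: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean signal profile across TUs with a bootstrap 95% confidence band.

    TUs are aligned at the TSS or at a supplied per-TU anchor (e.g. the
    pause site); with ``rescale_bins`` the TSS-to-anchor segment of each TU
    is linearly rescaled to a common number of bins instead.  TUs shorter
    than the flank are excluded (logged).
    """
    if len(tus) < 2:
        raise ValueError("metagene needs at least two TUs")
    rng = np.random.default_rng(seed)
    profiles = []
    for tu in tus:
        offset = 0
        if anchor == "pause_site":
            if anchors is None or tu.tu_id not in anchors:
                continue
            offset = int(anchors[tu.tu_id])
        if rescale_bins is not None:
            if anchor != "pause_site" or offset < 2:
                continue
            views = [tu_local_view(cov, tu, (0, offset)) for cov in coverages]
            sig = np.mean(views, axis=0)
            x = np.linspace(0, 1, sig.size)
            profiles.append(np.interp(np.linspace(0, 1, rescale_bins), x, sig))
            continue
        lo, hi = offset + flank[0], offset + flank[1]
        if lo < 0 or hi > tu.length:
            logger.debug("metagene: %s shorter than flank, excluded", tu.tu_id)
            continue
        views = [tu_local_view(cov, tu, (lo, hi)) for cov in coverages]
        profiles.append(np.mean(views, axis=0))
    if len(profiles) < 2:
        raise ValueError("fewer than two TUs cover the requested window")
    mat = np.vstack(profiles)
    mean = mat.mean(axis=0)
    boots = np.empty((n_boot, mat.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, mat.shape[0], mat.shape[0])
        boots[b] = mat[idx].mean(axis=0)
    lo_band, hi_band = np.percentile(boots, [2.5, 97.5], axis=0)
    pos = (
        np.arange(rescale_bins) if rescale_bins is not None
        else np.arange(flank[0], flank[1])
    )
    return pd.DataFrame({"position": pos, "mean": mean, "ci_lo": lo_band, "ci_hi": hi_band})


def report_correlates(kinetics: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Rank correlations between kinetic estimates and per-TU covariates.

    For every (kinetic, covariate) pair: Spearman rho with p-value, plus a
    two-sided Wilcoxon rank-sum test of the kinetic estimate between TUs
    below and above the covariate median.  Raw p-values, as in typical
    cohort-scale reports; constant covariates yield NA.
    """
    if len(kinetics) < 20:
        raise ValueError("need at least 20 TUs for cohort correlates")
    kin_cols = [c for c in kinetics.columns if kinetics[c].dtype.kind == "f"]
    rows = []
    joined = kinetics.join(covariates, how="inner", rsuffix="_cov")
    for cov_col in covariates.columns:
        cc = cov_col if cov_col in joined else f"{cov_col}_cov"
        for kin_col in kin_cols:
            sub = joined[[kin_col, cc]].dropna()
            if len(sub) < 5 or sub[cc].nunique() <= 1:
                rows.append(dict(kinetic=kin_col, covariate=cov_col, n=len(sub),
                                 spearman_rho=np.nan, spearman_p=np.nan,
                                 ranksum_stat=np.nan, ranksum_p=np.nan))
                continue
            rho = stats.spearmanr(sub[kin_col], sub[cc])
            split = sub[cc] > sub[cc].median()
            lo_grp, hi_grp = sub.loc[~split, kin_col], sub.loc[split, kin_col]
            if len(lo_grp) and len(hi_grp):
                rs = stats.ranksums(hi_grp, lo_grp)
                rs_stat, rs_p = float(rs.statistic), float(rs.pvalue)
            else:
                rs_stat = rs_p = np.nan
            rows.append(dict(kinetic=kin_col, covariate=cov_col, n=len(sub),
                             spearman_rho=float(rho.statistic), spearman_p=float(rho.pvalue),
                             ranksum_stat=rs_stat, ranksum_p=rs_p))
    return pd.DataFrame(rows)
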