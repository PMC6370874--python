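"""Synthetic tumor-only FFPE exome cohorts with full truth tracking.

The generator emulates the variant-call content of a tumor-only FFPE exome
study on the packaged toy genome:

* somatic hotspot drivers — one per driver-positive case, VAF = purity/2
  under a single-clone, diploid, copy-neutral model (stromal admixture
  dilutes the clonal heterozygous mutation), with binomial read sampling;
* germline SNPs — heterozygous near 50% and homozygous near 100% VAF, drawn
  from a shared catalogued site universe (so the known-SNP filter stage has
  something real to do);
* FFPE cytosine-deamination artifacts — low-VAF C>T calls with
  VAF ~ Beta(1.5, 40);
* per-site depths ~ negative binomial around a 116x exome mean;
* optional single copy-number events per case for the read-depth CNA module.

Every emitted record is traceable to exactly one truth category, and a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from ameloseq import refdata
from ameloseq.cna import CoverageProfile
from ameloseq.consequence import snv_for_protein_change
from ameloseq.formats import TargetInterval, VariantRecord, write_vcf
from ameloseq.somatic_filter import FilterConfig, rescue_at_hotspots, run_cascade


@dataclass
class SimConfig:
    """Study conditions for cohort simulation.

    Defaults encode the emulated study: HRAS drivers in 63% and BRAF in 8%
    of cases (mutually exclusive), tumor purity uniform on (0.2, 0.9) so
    clonal het driver VAFs span ~10-45%, and 116x mean target coverage.
    """

    n_cases: int = 24
    driver_freqs: tuple = (("HRAS", "Q61R", 0.63), ("BRAF", "V595E", 0.08))
    purity_range: tuple = (0.2, 0.9)
    mean_depth: float = 116.0
    depth_dispersion: float = 10.0  # negative-binomial shape; larger = tighter
    n_germline_het: int = 30
    n_germline_hom: int = 15
    artifact_rate: float = 20.0  # Poisson mean per case
    artifact_beta: tuple = (1.5, 40.0)
    n_snp_sites: int = 150  # size of the shared known-SNP site universe
    cna_event_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, _, f in self.driver_freqs)
        if not 0 <= total <= 1:
            raise ValueError("driver frequencies must sum to within [0, 1]")
        for _, _, f in self.driver_freqs:
            if not 0 <= f <= 1:
                raise ValueError("driver frequency outside [0, 1]")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("purity_range must be within (0, 1]")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated case."""

    case_id: str
    true_driver: Optional[tuple] = None  # (gene, protein_change)
    true_vaf: Optional[float] = None  # realized alt/depth at the driver site
    purity: Optional[float] = None
    germline_sites: list = field(default_factory=list)  # (chrom,pos,ref,alt,zygosity)
    artifact_sites: list = field(default_factory=list)  # (chrom,pos,ref,alt)
    cna_spans: list = field(default_factory=list)  # (chrom,start,end,log2)


@dataclass
class SimulatedCase:
    case_id: str
    variants: list  # of VariantRecord
    coverage: CoverageProfile
    truth: TruthRecord


@dataclass
class SimulatedCohort:
    config: SimConfig
    cases: list  # of SimulatedCase
    known_snp_sites: frozenset  # (chrom, pos, ref, alt)

    def truth_driver_count(self) -> int:
        return sum(1 for c in self.cases if c.truth.true_driver is not None)


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    # one stream per case: cohort resizing leaves earlier cases' output stable
    return np.random.default_rng(np.random.SeedSequence([seed, case_index + 1]))


def _nb_depth(rng, mean: float, shape: float, size=None):
    p = shape / (shape + mean)
    d = rng.negative_binomial(shape, p, size=size)
    return np.maximum(d, 1)


def _pick_alt(rng, ref: str) -> str:
    return str(rng.choice([b for b in "ACGT" if b != ref]))


def _on_target_positions(targets, genome) -> list:
    pos = []
    for iv in targets:
        limit = len(genome[iv.chrom])
        for p in range(iv.start, min(iv.end, limit)):
            pos.append((iv.chrom, p + 1))  # 1-based
    return pos


def simulate_cohort(cfg: SimConfig, outdir=None) -> SimulatedCohort:
    """Simulate a tumor-only cohort on the toy genome.

    Returns the in-memory cohort; when ``outdir`` is given, also writes one
    VCF and one coverage TSV per case, the truth table, the known-SNP VCF,
    and the capture-target BED.
    """
    genome = refdata.toy_genome()
    transcripts = {tx.gene_symbol: tx for tx in refdata.toy_transcripts()}
    targets = list(refdata.toy_targets())
    hotspot_loci = set(refdata.hotspot_loci())

    all_positions = _on_target_positions(targets, genome)
    usable = [
        (c, p)
        for c, p in all_positions
        if (c, p) not in hotspot_loci and genome[c][p - 1] in "ACGT"
    ]

    # shared known-SNP site universe (stream 0)
    rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    idx = rng0.choice(len(usable), size=min(cfg.n_snp_sites, len(usable)), replace=False)
    snp_sites = []
    for i in sorted(int(v) for v in idx):
        chrom, pos = usable[i]
        ref = genome[chrom][pos - 1]
        snp_sites.append((chrom, pos, ref, _pick_alt(rng0, ref)))
    snp_site_set = frozenset(snp_sites)

    # C positions for deamination artifacts, outside hotspots and SNP sites
    snp_pos = {(c, p) for c, p, _, _ in snp_sites}
    c_positions = [
        (c, p) for c, p in usable if genome[c][p - 1] == "C" and (c, p) not in snp_pos
    ]

    driver_cum = []
    acc = 0.0
    for gene, pchange, freq in cfg.driver_freqs:
        acc += freq
        driver_cum.append((gene, pchange, acc))

    cases = []
    for i in range(cfg.n_cases):
        rng = _case_rng(cfg.seed, i)
        case_id = f"SIM-{i + 1:03d}"
        truth = TruthRecord(case_id=case_id)
        variants: list[VariantRecord] = []

        purity = rng.uniform(*cfg.purity_range)
        truth.purity = float(purity)

        u = rng.uniform()
        driver = next(((g, pc) for g, pc, cum in driver_cum if u < cum), None)
        if driver is not None:
            gene, pchange = driver
            ref_aa, ppos, alt_aa = pchange[0], int(pchange[1:-1]), pchange[-1]
            chrom, pos, ref, alt = snv_for_protein_change(
                transcripts[gene], genome, ppos, ref_aa, alt_aa
            )
            depth = int(_nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion))
            alt_reads = int(rng.binomial(depth, purity / 2.0))
            truth.true_driver = (gene, pchange)
            truth.true_vaf = alt_reads / depth
            if alt_reads >= 1:
                variants.append(
                    VariantRecord(chrom, pos, ref, alt, depth, alt_reads, sample_id=case_id)
                )

        # germline SNPs from the shared universe
        n_gl = min(cfg.n_germline_het + cfg.n_germline_hom, len(snp_sites))
        gl_idx = rng.choice(len(snp_sites), size=n_gl, replace=False)
        for k, j in enumerate(sorted(int(v) for v in gl_idx)):
            chrom, pos, ref, alt = snp_sites[j]
            zyg = "het" if k < cfg.n_germline_het else "hom"
            p_alt = 0.5 if zyg == "het" else 0.98
            depth = int(_nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion))
            alt_reads = int(rng.binomial(depth, p_alt))
            truth.germline_sites.append((chrom, pos, ref, alt, zyg))
            if alt_reads >= 1:
                variants.append(
                    VariantRecord(chrom, pos, ref, alt, depth, alt_reads, sample_id=case_id)
                )

        # FFPE deamination artifacts: low-VAF C>T
        n_art = int(rng.poisson(cfg.artifact_rate))
        if n_art and c_positions:
            art_idx = rng.choice(len(c_positions), size=min(n_art, len(c_positions)), replace=False)
            for j in sorted(int(v) for v in art_idx):
                chrom, pos = c_positions[j]
                vaf = float(rng.beta(*cfg.artifact_beta))
                depth = int(_nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion))
                alt_reads = int(rng.binomial(depth, vaf))
                if alt_reads >= 1:
                    truth.artifact_sites.append((chrom, pos, "C", "T"))
                    variants.append(
                        VariantRecord(chrom, pos, "C", "T", depth, alt_reads, sample_id=case_id)
                    )

        # per-target coverage, with an optional single copy-number event
        cn_mult = np.ones(len(targets))
        if cfg.cna_event_prob > 0 and rng.uniform() < cfg.cna_event_prob:
            span = max(2, int(0.2 * len(targets)))
            start = int(rng.integers(0, len(targets) - span + 1))
            mult = float(rng.choice([0.5, 1.5]))
            cn_mult[start : start + span] = mult
            truth.cna_spans.append(
                (
                    targets[start].chrom,
                    targets[start].start,
                    targets[start + span - 1].end,
                    float(np.log2(mult)),
                )
            )
        depths = _nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion, size=len(targets)) * cn_mult
        coverage = CoverageProfile(
            sample_id=case_id, bins=[(iv, float(d)) for iv, d in zip(targets, depths)]
        )

        variants.sort(key=lambda v: (v.chrom, v.pos, v.alt_allele))
        cases.append(SimulatedCase(case_id, variants, coverage, truth))

    cohort = SimulatedCohort(config=cfg, cases=cases, known_snp_sites=snp_site_set)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write per-case VCFs and coverage TSVs, truth TSV, known-SNP VCF, BED."""
    from ameloseq.cna import write_coverage_tsv
    from ameloseq.formats import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = refdata.toy_genome()
    contigs = sorted(genome)
    for case in cohort.cases:
        write_vcf(case.variants, outdir / f"{case.case_id}.vcf", contigs=contigs)
        write_coverage_tsv(case.coverage, outdir / f"{case.case_id}.coverage.tsv")
    write_bed(list(refdata.toy_targets()), outdir / "targets.bed")

    snp_records = [
        VariantRecord(c, p, r, a, None, None, sample_id="sites")
        for c, p, r, a in sorted(cohort.known_snp_sites)
    ]
    write_vcf(snp_records, outdir / "known_snps.vcf", contigs=contigs)

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "case_id\tcategory\tchrom\tstart\tend\tref\talt\tvaf\tpurity\tgene\tprotein_change\n"
        )
        for case in cohort.cases:
            t = case.truth
            if t.true_driver is not None:
                gene, pc = t.true_driver
                fh.write(
                    f"{t.case_id}\tdriver\t\t\t\t\t\t{t.true_vaf:.4f}\t{t.purity:.4f}\t{gene}\t{pc}\n"
                )
            for chrom, pos, ref, alt, zyg in t.germline_sites:
                fh.write(
                    f"{t.case_id}\tgermline_{zyg}\t{chrom}\t{pos}\t{pos}\t{ref}\t{alt}\t\t\t\t\n"
                )
            for chrom, pos, ref, alt in t.artifact_sites:
                fh.write(f"{t.case_id}\tartifact\t{chrom}\t{pos}\t{pos}\t{ref}\t{alt}\t\t\t\t\n")
            for chrom, s, e, log2 in t.cna_spans:
                fh.write(f"{t.case_id}\tcna\t{chrom}\t{s}\t{e}\t\t\t{log2:.3f}\t\t\t\n")


# ---------------------------------------------------------------------------
# CNA profile simulation (read-depth module validation)
# ---------------------------------------------------------------------------

def simulate_cna_profiles(
    n_profiles: int = 16,
    n_aberrant: int = 1,
    n_bins: int = 300,
    event_bins: int = 30,
    event_log2: float = 0.585,
    mean_depth: float = 116.0,
    depth_dispersion: float = 200.0,  # near-Poisson: counting noise dominates
    capture_sd: float = 0.3,
    seed: int = 0,
):
    """Simulate a cohort of coverage profiles, a few carrying one CN event.

    Per-bin capture efficiencies (log-normal, shared across samples) emulate
    target-specific bias that cohort-panel normalization must cancel. Returns
    (profiles, truth) where truth maps aberrant sample ids to their
    (start_bin, end_bin, log2) event.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    eff = np.exp(rng.normal(0.0, capture_sd, size=n_bins))
    intervals = [TargetInterval("simchr", i * 100, (i + 1) * 100, f"bin{i}") for i in range(n_bins)]
    profiles, truth = [], {}
    for s in range(n_profiles):
        sid = f"CNASIM-{s + 1:02d}"
        mult = np.ones(n_bins)
        if s < n_aberrant:
            start = int(rng.integers(5, n_bins - event_bins - 5))
            mult[start : start + event_bins] = 2.0**event_log2
            truth[sid] = (start, start + event_bins, event_log2)
        means = mean_depth * eff * mult
        depths = np.array(
            [float(_nb_depth(rng, m, depth_dispersion)) for m in means]
        )
        profiles.append(
            CoverageProfile(sample_id=sid, bins=list(zip(intervals, depths)))
        )
    return profiles, truth


# ---------------------------------------------------------------------------
# End-to-end validation harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Sensitivity/specificity of the full cascade against simulated truth."""

    n_cases: int
    n_true_driver: int
    n_detected_true: int
    n_false_positive_cases: int
    n_artifact_nominations: int
    sensitivity: float
    specificity: float
    estimated_driver_freq: float
    truth_freq: float
    ci_low: float  # 95% binomial CI of the configured truth frequency
    ci_high: float
    within_ci: bool

    def to_dict(self) -> dict:
        return asdict(self)


def binomial_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Central binomial interval for the observed frequency under truth p."""
    lo, hi = stats.binom.interval(level, n, p)
    return float(lo) / n, float(hi) / n


def end_to_end_recovery(
    cfg: SimConfig, rescue: bool = True, filter_cfg: Optional[FilterConfig] = None
) -> RecoveryReport:
    """Simulate a cohort, run the full cascade (+ rescue), score vs truth.

    A case counts as detected when at least one of its variants is nominated
    or rescued; it is a false positive when a driver-negative case has any
    accepted variant. Artifact nominations are accepted variants at simulated
    FFPE-artifact sites (expected: zero).
    """
    cohort = simulate_cohort(cfg)
    if filter_cfg is None:
        filter_cfg = FilterConfig(
            gene_list=refdata.demo_gene_list(), known_snp_sites=frozenset(cohort.known_snp_sites)
        )
    else:
        filter_cfg = FilterConfig(
            **{
                **asdict_shallow(filter_cfg),
                "known_snp_sites": frozenset(cohort.known_snp_sites),
            }
        )
    loci = set(refdata.hotspot_loci())

    n_true = n_det = n_fp_cases = n_art = 0
    for case in cohort.cases:
        traces = run_cascade(
            case.variants, filter_cfg, refdata.consequence_fn, refdata.hotspot_fn
        )
        if rescue:
            traces = rescue_at_hotspots(traces, filter_cfg, loci)
        accepted = [t for t in traces if t.accepted]
        art_sites = {(c, p) for c, p, _, _ in case.truth.artifact_sites}
        n_art += sum(1 for t in accepted if t.variant.site in art_sites)
        has_truth = case.truth.true_driver is not None
        detected = bool(accepted)
        if has_truth:
            n_true += 1
            if detected:
                n_det += 1
        elif detected:
            n_fp_cases += 1

    n = len(cohort.cases)
    truth_freq = sum(f for _, _, f in cfg.driver_freqs)
    est = (n_det + n_fp_cases) / n if n else 0.0
    lo, hi = binomial_ci(truth_freq, n) if n else (0.0, 1.0)
    n_neg = n - n_true
    return RecoveryReport(
        n_cases=n,
        n_true_driver=n_true,
        n_detected_true=n_det,
        n_false_positive_cases=n_fp_cases,
        n_artifact_nominations=n_art,
        sensitivity=n_det / n_true if n_true else float("nan"),
        specificity=(n_neg - n_fp_cases) / n_neg if n_neg else float("nan"),
        estimated_driver_freq=est,
        truth_freq=truth_freq,
        ci_low=lo,
        ci_high=hi,
        within_ci=bool(lo <= est <= hi),
    )


def asdict_shallow(cfg: FilterConfig) -> dict:
    return {
        "min_depth": cfg.min_depth,
        "vaf_low": cfg.vaf_low,
        "vaf_high": cfg.vaf_high,
        "rescue_vaf_floor": cfg.rescue_vaf_floor,
        "rescue_min_alt_reads": cfg.rescue_min_alt_reads,
        "gene_list": cfg.gene_list,
        "known_snp_sites": cfg.known_snp_sites,
        "hotspot_only": cfg.hotspot_only,
    }
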