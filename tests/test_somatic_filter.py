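"""Filtering cascade: evidence band, stage ordering, oracle equivalence,
monotonicity, and the low-VAF hotspot rescue."""

import numpy as np
import pytest

from ameloseq.consequence import ConsequenceCall
from ameloseq.formats import VariantRecord
from ameloseq.somatic_filter import (
    STAGES,
    FilterConfig,
    evidence_filter,
    rescue_at_hotspots,
    run_cascade,
)

GENES = ["HRAS", "BRAF", "KRAS", "OBSCURE1", "OBSCURE2"]
GENE_LIST = frozenset({"HRAS", "BRAF", "KRAS"})
CLASSES = ["missense", "stop_gain", "splice_donor", "synonymous", "intronic", "noncoding"]
HIGH = {"missense", "stop_gain", "splice_donor", "splice_acceptor"}


def make_cfg(**kw):
    kw.setdefault("gene_list", GENE_LIST)
    return FilterConfig(**kw)


def synth_variant(rng, i):
    """A labeled synthetic variant with attributes drawn to exercise every stage."""
    depth = int(rng.integers(5, 250))
    alt = int(rng.integers(0, depth + 1))
    v = VariantRecord("chr1", 1000 + i, "A", "G", depth, alt, sample_id="S")
    v.annotations["_gene"] = str(rng.choice(GENES))
    v.annotations["_class"] = str(rng.choice(CLASSES))
    v.annotations["_hotspot"] = bool(rng.uniform() < 0.5)
    v.annotations["_known_snp"] = bool(rng.uniform() < 0.3)
    return v


def stub_consequence_fn(v):
    klass = v.annotations["_gene"] and v.annotations["_class"]
    ppos = 61 if klass in ("missense", "stop_gain") else None
    return ConsequenceCall(
        variant=v, transcript_id="t", gene_symbol=v.annotations["_gene"], klass=klass,
        protein_pos=ppos, ref_aa="Q" if ppos else None,
        alt_aa=("R" if klass == "missense" else "*") if ppos else None,
    )


def stub_hotspot_fn(call):
    from ameloseq.hotspot_map import HotspotEntry

    if call.variant.annotations["_hotspot"] and call.klass == "missense":
        return HotspotEntry(call.gene_symbol or "HRAS", 61, "Q")
    return None


def snp_sites_of(variants):
    return frozenset(v.site_allele for v in variants if v.annotations["_known_snp"])


def brute_force_survivors(variants, cfg):
    """Ten-line independent reimplementation of the five conjunctive rules."""
    surv = set()
    for v in variants:
        if v.annotations["_gene"] not in cfg.gene_list:
            continue
        if v.site_allele in cfg.known_snp_sites:
            continue
        if v.total_depth is None or v.total_depth < cfg.min_depth:
            continue
        if not (cfg.vaf_low <= v.vaf <= cfg.vaf_high):
            continue
        if v.annotations["_class"] not in HIGH:
            continue
        if cfg.hotspot_only and not (v.annotations["_hotspot"] and v.annotations["_class"] == "missense"):
            continue
        surv.add(id(v))
    return surv


class TestEvidenceFilter:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (72, 20, True),  # VAF 0.278: the typical nominated driver
            (101, 11, False),  # VAF 0.109: the low-purity miss
            (19, 6, False),  # depth boundary: 19 < 20
            (20, 4, True),  # inclusive boundaries: depth 20, VAF exactly 0.20
            (20, 10, True),  # VAF exactly 0.50
            (100, 51, False),  # VAF above band: looks germline het
            (100, 98, False),  # germline hom territory
        ],
    )
    def test_band_with_inclusive_endpoints(self, depth, alt, expected):
        v = VariantRecord("chr1", 1, "A", "G", depth, alt)
        passed, _ = evidence_filter(v, make_cfg())
        assert passed is expected

    def test_unknown_depth_fails_with_reason(self):
        v = VariantRecord("chr1", 1, "A", "G", None, None)
        passed, reason = evidence_filter(v, make_cfg())
        assert not passed and reason == "no-evidence"


class TestFilterConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterConfig(rescue_vaf_floor=0.25)  # floor above vaf_low
        with pytest.raises(ValueError):
            FilterConfig(vaf_low=0.6, vaf_high=0.5)
        with pytest.raises(ValueError):
            FilterConfig(min_depth=0)


class TestRunCascade:
    def test_hotspot_driver_is_nominated(self):
        v = VariantRecord("chr1", 402, "A", "G", 72, 20, sample_id="CAA-03")
        v.annotations.update(_gene="HRAS", _class="missense", _hotspot=True, _known_snp=False)
        (trace,) = run_cascade([v], make_cfg(), stub_consequence_fn, stub_hotspot_fn)
        assert trace.final_status == "nominated"
        assert all(trace.stage_results[s] == "pass" for s in STAGES)

    def test_gene_not_in_list_rejected_with_na_downstream(self):
        v = VariantRecord("chr1", 402, "A", "G", 72, 20)
        v.annotations.update(_gene="OBSCURE1", _class="missense", _hotspot=True, _known_snp=False)
        (trace,) = run_cascade([v], make_cfg(), stub_consequence_fn, stub_hotspot_fn)
        assert trace.final_status == "rejected(gene_list)"
        assert all(trace.stage_results[s] == "NA" for s in STAGES[1:])

    def test_known_snp_excluded(self):
        v = VariantRecord("chr1", 402, "A", "G", 72, 30)
        v.annotations.update(_gene="HRAS", _class="missense", _hotspot=True, _known_snp=True)
        cfg = make_cfg(known_snp_sites=snp_sites_of([v]))
        (trace,) = run_cascade([v], cfg, stub_consequence_fn, stub_hotspot_fn)
        assert trace.final_status == "rejected(known_snp)"

    def test_oracle_equivalence_on_1000_random_variants(self):
        rng = np.random.default_rng(42)
        variants = [synth_variant(rng, i) for i in range(1000)]
        cfg = make_cfg(known_snp_sites=snp_sites_of(variants))
        traces = run_cascade(variants, cfg, stub_consequence_fn, stub_hotspot_fn)
        got = {id(t.variant) for t in traces if t.final_status == "nominated"}
        assert got == brute_force_survivors(variants, cfg)

    def test_survivor_set_invariant_under_permutation(self):
        rng = np.random.default_rng(1)
        variants = [synth_variant(rng, i) for i in range(200)]
        cfg = make_cfg(known_snp_sites=snp_sites_of(variants))
        t1 = run_cascade(variants, cfg, stub_consequence_fn, stub_hotspot_fn)
        perm = list(variants)
        rng.shuffle(perm)
        t2 = run_cascade(perm, cfg, stub_consequence_fn, stub_hotspot_fn)
        surv = lambda ts: {id(t.variant) for t in ts if t.accepted}
        assert surv(t1) == surv(t2)

    @pytest.mark.parametrize(
        "tight",
        [
            dict(min_depth=40),
            dict(vaf_low=0.25),
            dict(vaf_high=0.45),
            dict(min_depth=60, vaf_low=0.3, vaf_high=0.4),
        ],
    )
    def test_monotonicity_tightening_never_enlarges(self, tight):
        rng = np.random.default_rng(2)
        variants = [synth_variant(rng, i) for i in range(500)]
        snps = snp_sites_of(variants)
        base = make_cfg(known_snp_sites=snps)
        tighter = make_cfg(known_snp_sites=snps, **tight)
        surv = lambda cfg: {
            id(t.variant)
            for t in run_cascade(variants, cfg, stub_consequence_fn, stub_hotspot_fn)
            if t.accepted
        }
        assert surv(tighter) <= surv(base)

    def test_hotspot_only_false_gives_superset(self):
        rng = np.random.default_rng(3)
        variants = [synth_variant(rng, i) for i in range(300)]
        snps = snp_sites_of(variants)
        surv = lambda cfg: {
            id(t.variant)
            for t in run_cascade(variants, cfg, stub_consequence_fn, stub_hotspot_fn)
            if t.accepted
        }
        assert surv(make_cfg(known_snp_sites=snps)) <= surv(
            make_cfg(known_snp_sites=snps, hotspot_only=False)
        )


HOTSPOT_LOCI = {("chr1", 402)}


class TestRescue:
    def low_vaf_driver(self, pos=402, depth=101, alt=11):
        v = VariantRecord("chr1", pos, "A", "G", depth, alt, sample_id="CAA-20")
        v.annotations.update(_gene="HRAS", _class="missense", _hotspot=True, _known_snp=False)
        return v

    def run(self, v, loci=HOTSPOT_LOCI, cfg=None):
        cfg = cfg or make_cfg()
        traces = run_cascade([v], cfg, stub_consequence_fn, stub_hotspot_fn)
        return rescue_at_hotspots(traces, cfg, loci)[0]

    def test_low_vaf_case_at_hotspot_is_rescued(self):
        # depth 101, 11 alt reads, VAF 0.109: below band, above rescue floor
        trace = self.run(self.low_vaf_driver())
        assert trace.final_status == "rescued"

    def test_same_vaf_off_hotspot_stays_rejected(self):
        trace = self.run(self.low_vaf_driver(pos=999))
        assert trace.final_status == "rejected(evidence)"

    def test_vaf_below_rescue_floor_stays_rejected(self):
        trace = self.run(self.low_vaf_driver(depth=100, alt=2))
        assert trace.final_status == "rejected(evidence)"

    def test_too_few_alt_reads_stays_rejected(self):
        trace = self.run(self.low_vaf_driver(depth=40, alt=3))  # VAF 0.075 >= floor
        assert trace.final_status == "rejected(evidence)"

    def test_above_band_not_rescued(self):
        trace = self.run(self.low_vaf_driver(depth=100, alt=80))
        assert trace.final_status == "rejected(evidence)"

    def test_rescue_never_demotes(self):
        rng = np.random.default_rng(4)
        variants = [synth_variant(rng, i) for i in range(300)]
        cfg = make_cfg(known_snp_sites=snp_sites_of(variants))
        traces = run_cascade(variants, cfg, stub_consequence_fn, stub_hotspot_fn)
        loci = {v.site for v in variants[::3]}
        rescued = rescue_at_hotspots(traces, cfg, loci)
        for before, after in zip(traces, rescued):
            if before.accepted:
                assert after.final_status == before.final_status
            else:
                assert after.final_status in (before.final_status, "rescued")

    def test_brute_force_oracle_with_rescue_rule(self):
        rng = np.random.default_rng(5)
        variants = [synth_variant(rng, i) for i in range(500)]
        cfg = make_cfg(known_snp_sites=snp_sites_of(variants))
        loci = {v.site for v in variants if v.annotations["_hotspot"]}
        traces = rescue_at_hotspots(
            run_cascade(variants, cfg, stub_consequence_fn, stub_hotspot_fn), cfg, loci
        )
        got = {id(t.variant) for t in traces if t.accepted}
        expected = brute_force_survivors(variants, cfg)
        for v in variants:  # extend the oracle with the rescue rule
            if (
                v.annotations["_gene"] in cfg.gene_list
                and v.site_allele not in cfg.known_snp_sites
                and v.site in loci
                and v.vaf is not None
                and not (
                    v.total_depth >= cfg.min_depth and cfg.vaf_low <= v.vaf <= cfg.vaf_high
                )
                and cfg.rescue_vaf_floor <= v.vaf <= cfg.vaf_high
                and v.alt_depth >= cfg.rescue_min_alt_reads
            ):
                expected.add(id(v))
        assert got == expected
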