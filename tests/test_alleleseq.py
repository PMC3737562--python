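"""SNP demultiplexing, primer trimming, exact fragment-end mapping."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import binom

from allele4c.alleleseq import (
    ViewpointSpec,
    demultiplex_and_map,
    enforce_se_allele,
    map_se_reads,
    map_to_fragment_ends,
    split_by_snp,
    trim_primer,
)
from allele4c.fragmentome import RFLPSite
from allele4c.synthetic_data import ReadSimSpec, simulate_reads


def _tiny_vp(**kw) -> ViewpointSpec:
    base = dict(
        name="vp", chrom="c", pos=100, strategy="PE",
        p1_start=80, p1_end=100, p1_seq="ACGTACGTAC",
        p2_start=10, p2_end=46, snp_offset=3, base_a="A", base_b="G",
    )
    base.update(kw)
    return ViewpointSpec(**base)


class TestSplitBySnp:
    VP = _tiny_vp()

    def test_assignment_by_single_base(self):
        pairs = [
            ("r1", "X", "CCCACCC"),  # base A at offset 3
            ("r2", "X", "CCCGCCC"),  # base B
            ("r3", "X", "CCCTCCC"),  # neither
            ("r4", "X", "cccaccc"),  # case-insensitive A
        ]
        pools = split_by_snp(pairs, self.VP)
        assert [r for r, _ in pools.pools["A"]] == ["r1", "r4"]
        assert [r for r, _ in pools.pools["B"]] == ["r2"]
        assert [r for r, _ in pools.pools["ambiguous"]] == ["r3"]

    def test_n_base_ambiguous(self):
        pools = split_by_snp([("r", "X", "CCCNCCC")], self.VP)
        assert pools.sizes == {"A": 0, "B": 0, "ambiguous": 1}

    def test_short_read2_distinct_reason(self):
        pools = split_by_snp([("r", "X", "CC")], self.VP)
        assert pools.pools["ambiguous"] == [("r", "X")]
        assert pools.reasons["read2-too-short"] == 1

    def test_partition_exhaustive_and_disjoint(self, scen, lym_sim):
        pools = split_by_snp(lym_sim.pairs(), scen.viewpoint)
        total = sum(pools.sizes.values())
        assert total == len(lym_sim.ids)
        ids = [r for pool in pools.pools.values() for r, _ in pool]
        assert len(set(ids)) == total

    def test_error_free_split_matches_truth(self, scen, lym_sim):
        pools = split_by_snp(lym_sim.pairs(), scen.viewpoint)
        truth = dict(zip(lym_sim.truth["read_id"], lym_sim.truth["allele"]))
        assert pools.sizes["ambiguous"] == 0
        for allele in ("A", "B"):
            assert all(truth[r] == allele for r, _ in pools.pools[allele])

    def test_error_rate_misassignment_within_binomial_ci(self, scen):
        # a substitution at the SNP base leaves the correct pool with
        # probability e; it lands in the other allele's pool 1/3 of the
        # time and in the ambiguous pool 2/3 of the time
        e = 0.01
        n = 10_000
        sim = simulate_reads(
            scen.hap, scen.models["lymphoid"], scen.dbs,
            ReadSimSpec(n_reads=n, error_rate=e, seed=314), scen.viewpoint,
        )
        pools = split_by_snp(sim.pairs(), scen.viewpoint)
        truth = dict(zip(sim.truth["read_id"], sim.truth["allele"]))
        wrong = sum(
            1
            for allele in ("A", "B")
            for r, _ in pools.pools[allele]
            if truth[r] != allele
        )
        ambiguous = pools.sizes["ambiguous"]
        for count, rate in ((wrong, e / 3), (ambiguous, 2 * e / 3)):
            lo, hi = binom.ppf([0.0025, 0.9975], n, rate)
            assert lo <= count <= hi, (count, rate)


class TestTrimPrimer:
    VP = _tiny_vp()

    def test_exact_prefix_removed(self):
        t, reason = trim_primer("ACGTACGTAC" + "T" * 16, self.VP)
        assert t == "T" * 16 and reason == "ok"

    def test_single_mismatch_rejected(self):
        t, reason = trim_primer("ACGTACGTAG" + "T" * 16, self.VP)
        assert t is None and reason == "primer-mismatch"

    def test_short_remainder_rejected(self):
        t, reason = trim_primer("ACGTACGTAC" + "T" * 5, self.VP)
        assert t is None and reason == "too-short"

    def test_trimmed_reads_refound_in_truth_end_sequences(self, scen, lym_sim):
        truth = lym_sim.truth
        for (rid, r1, _), allele, eid in zip(
            lym_sim.pairs()[:1000], truth["allele"][:1000], truth["frag_end_id"][:1000]
        ):
            t, reason = trim_primer(r1, scen.viewpoint)
            if t is None:
                assert reason == "too-short"
                continue
            oriented = scen.dbs[allele].oriented_sequence(int(eid))
            assert oriented.startswith(t)


class TestMapping:
    def test_zero_reads_zero_table(self, scen):
        table = map_to_fragment_ends([], scen.dbs["A"])
        assert table.counts.sum() == 0
        assert table.totals == {
            "input": 0, "mapped": 0, "unmapped": 0,
            "multi_discarded": 0, "blind_discarded": 0,
        }

    def test_single_substitution_unmapped(self, scen):
        db = scen.dbs["A"]
        eid = int(np.nonzero(db.analyzable)[0][10])
        key = db.mapping_key(eid)
        flipped = ("A" if key[5] != "A" else "C")
        mutant = key[:5] + flipped + key[6:]
        table = map_to_fragment_ends([("r", mutant)], db)
        assert table.totals["unmapped"] == 1 and table.counts.sum() == 0

    def test_empty_db_rejected(self, scen):
        import copy

        db = copy.copy(scen.dbs["A"])
        db.ends = db.ends.iloc[0:0]
        with pytest.raises(ValueError):
            map_to_fragment_ends([("r", "ACGT" * 4)], db)

    def test_blind_ends_never_incremented(self, scen, lym_tables):
        for table in lym_tables.values():
            blind = scen.dbs[table.allele].ends["blind"].to_numpy()
            assert table.counts[blind].sum() == 0

    def test_accounting_identity(self, lym_sim, lym_tables):
        total = sum(
            v for t in lym_tables.values() for k, v in t.totals.items() if k != "input"
        )
        assert total == len(lym_sim.ids)
        for t in lym_tables.values():
            t.check_accounting()

    def test_allele_label_swap_symmetry(self, scen):
        sim = simulate_reads(
            scen.hap, scen.models["lymphoid"], scen.dbs,
            ReadSimSpec(n_reads=2000, seed=99), scen.viewpoint,
        )
        vp = scen.viewpoint
        tables = demultiplex_and_map(sim.pairs(), vp, scen.dbs)
        vp_swapped = replace(vp, base_a=vp.base_b, base_b=vp.base_a)
        swapped = demultiplex_and_map(
            sim.pairs(), vp_swapped, {"A": scen.dbs["B"], "B": scen.dbs["A"]}
        )
        np.testing.assert_array_equal(tables["A"].counts, swapped["B"].counts)
        np.testing.assert_array_equal(tables["B"].counts, swapped["A"].counts)

    def test_error_free_mapped_fraction_complete(self, scen):
        # every pair with a mappable (>= 12 bp) capture is mapped or
        # deliberately discarded (blind target); none is unmapped
        for table in demultiplex_and_map(
            simulate_reads(
                scen.hap, scen.models["lymphoid"], scen.dbs,
                ReadSimSpec(n_reads=5000, seed=17), scen.viewpoint,
            ).pairs(),
            scen.viewpoint,
            scen.dbs,
        ).values():
            assert table.totals["unmapped"] == 0
            assert table.totals["multi_discarded"] == 0


class TestSingleEnd:
    def test_retained_allele_tagging(self, scen):
        reads = [("r1", "ACGT"), ("r2", "TTTT")]
        tagged, retained, note = enforce_se_allele(reads, scen.se_viewpoint)
        assert tagged == reads
        assert retained == "A"  # the site is gained on B
        assert "allele B" in note and "allele A" in note

    def test_empty_reads(self, scen):
        tagged, retained, _ = enforce_se_allele([], scen.se_viewpoint)
        assert tagged == [] and retained == "A"

    def test_missing_rflp_rejected(self):
        vp = _tiny_vp()
        with pytest.raises(ValueError):
            enforce_se_allele([], vp, None)

    def test_se_viewpoint_requires_rflp(self):
        with pytest.raises(ValueError, match="RFLPSite"):
            _tiny_vp(strategy="SE", rflp=None)

    def test_excluded_allele_reads_fail_viewpoint_match(self, scen):
        vp = scen.se_viewpoint
        read_len = len(vp.p1_seq) + scen.dbs["A"].map_prefix_len
        sim = simulate_reads(
            scen.hap, scen.models["lymphoid"], scen.dbs,
            ReadSimSpec(n_reads=2000, strategy="SE", read_len=read_len, seed=55),
            vp,
        )
        truth = dict(zip(sim.truth["read_id"], sim.truth["allele"]))
        for rid, seq in sim.single():
            trimmed, reason = trim_primer(seq, vp)
            if truth[rid] == "B":
                assert reason == "primer-mismatch"
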