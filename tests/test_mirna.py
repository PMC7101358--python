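import numpy as np
import pytest

from saltlnc.core import Transcript, reverse_complement
from saltlnc.mirna import (
    TargetScoring,
    annotate_premirnas,
    hairpin_check,
    mirna_family,
    normalize_precursor_name,
    nussinov_max_pairs,
    pairwise_specific_families,
    predict_targets,
    regulation_summary,
    site_expectation,
    summarize_mirna_tables,
    TargetHit,
)
from saltlnc.simulate import generate_target_set, table1_fixture

from .oracles import enumerate_max_pairs
from .test_align import plant_segment, random_transcript


class TestFamilyNaming:
    @pytest.mark.parametrize(
        "name,family",
        [
            ("mir396a", "mir396"),
            ("mir166g", "mir166"),
            ("mir477", "mir477"),
            ("ath-miR156g-5p", "mir156"),
            ("pve-mir397a", "mir397"),
        ],
    )
    def test_examples(self, name, family):
        assert mirna_family(name) == family

    def test_idempotent(self):
        for name in ("mir396a", "osa-miR159a-3p", "mir408"):
            fam = mirna_family(name)
            assert mirna_family(fam) == fam

    def test_unparseable_name_is_an_error(self):
        with pytest.raises(ValueError, match="not-a-mirna"):
            mirna_family("not-a-mirna")

    def test_precursor_normalization(self):
        assert normalize_precursor_name("ath-miR156g-5p") == "mir156g-5p"
        assert normalize_precursor_name("pve-mir396a") == "mir396a"


class TestNussinov:
    def test_simple_stem(self):
        max_pairs, pairs = nussinov_max_pairs("GGGAAAACCC")
        assert max_pairs == 3
        assert pairs == [(0, 9), (1, 8), (2, 7)]

    def test_matches_exhaustive_enumeration(self):
        """DP equals brute-force enumeration over all nested pairings for
        100 seeded sequences of length <= 12."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n)).replace("U", "T")
            dp, pairs = nussinov_max_pairs(seq)
            assert dp == enumerate_max_pairs(seq)
            assert len(pairs) == dp

    def test_structure_is_balanced_and_loops_legal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
            _, pairs = nussinov_max_pairs(seq)
            for i, j in pairs:
                assert j - i - 1 >= 3


class TestHairpinCheck:
    def make_hairpin(self, rng, stem=20, loop=6, flank=40):
        stem_seq = "".join(rng.choice(list("ACGT"), size=stem))
        loop_seq = "".join(rng.choice(list("ACGT"), size=loop))
        core = stem_seq + loop_seq + reverse_complement(stem_seq)
        f5 = "".join(rng.choice(list("ACGT"), size=flank))
        f3 = "".join(rng.choice(list("ACGT"), size=flank))
        return f5 + core + f3

    def test_planted_hairpin_passes_defaults(self):
        rng = np.random.default_rng(2)
        seq = self.make_hairpin(rng, stem=20, loop=6, flank=37)  # 120 nt
        result = hairpin_check(seq)
        assert result.passes and result.longest_stem >= 15

    def test_length_gate(self):
        assert not hairpin_check("GGGAAAACCC").passes  # too short
        assert "length" in hairpin_check("A" * 500).reason

    def test_unstructured_sequence_fails(self):
        result = hairpin_check("A" * 60)
        assert not result.passes and result.max_pairs == 0


class TestTableSummaries:
    def test_packaged_table_counts(self):
        table = table1_fixture()
        summary = summarize_mirna_tables(table)
        assert summary.per_contrast_entries == {"St6-Sc": 9, "Gt6-Gc": 8, "Gt24-Gc": 10}
        assert summary.per_contrast_families == {"St6-Sc": 7, "Gt6-Gc": 7, "Gt24-Gc": 8}
        assert summary.pooled_distinct_precursors == 14
        assert summary.pooled_distinct_families == 11

    def test_genotype_specific_families(self):
        summary = summarize_mirna_tables(table1_fixture())
        assert summary.specific_families["St6-Sc"] == {"mir160", "mir397"}
        assert summary.specific_families["Gt24-Gc"] == {"mir164", "mir167"}
        fs = summary.family_sets
        assert pairwise_specific_families(fs, "Gt6-Gc", "St6-Sc") == {"mir393", "mir477"}
        assert pairwise_specific_families(fs, "Gt24-Gc", "Gt6-Gc") == {"mir164", "mir167"}

    def test_every_packaged_name_parses(self):
        for entries in table1_fixture().values():
            for _, name in entries:
                assert mirna_family(name).startswith("mir")

    def test_specific_plus_shared_partition_each_contrast(self):
        summary = summarize_mirna_tables(table1_fixture())
        for contrast, fams in summary.family_sets.items():
            specific = summary.specific_families[contrast]
            shared = fams - specific
            assert specific | shared == fams and not specific & shared

    def test_empty_annotations(self):
        summary = summarize_mirna_tables({"Gt6-Gc": []})
        assert summary.pooled_distinct_precursors == 0
        assert summary.per_contrast_families == {"Gt6-Gc": 0}

    def test_known_entry_present(self):
        assert ("lncRNA_PveLR6504", "mir393b") in table1_fixture()["Gt6-Gc"]


class TestAnnotation:
    def test_embedded_hairpin_annotated(self, synth):
        lnc_labels = {"LNCRNA", "PRE_MIRNA_LNCRNA", "CONSERVED_LNCRNA"}
        lnc = [t for t in synth.transcripts if synth.truth.labels[t.id] in lnc_labels]
        annotations = annotate_premirnas(lnc, synth.refs.hairpin_db)
        got = {(a.lnc_id, a.precursor_name) for a in annotations}
        assert got == set(synth.truth.premirnas.items())
        assert all(a.hairpin_ok for a in annotations)
        assert all(a.family == mirna_family(a.precursor_name) for a in annotations)

    def test_empty_db_annotates_nothing(self):
        rng = np.random.default_rng(3)
        assert annotate_premirnas([random_transcript(rng, "t", 300)], []) == []

    def test_degraded_hairpin_not_annotated(self, synth):
        rng = np.random.default_rng(4)
        hairpin = synth.refs.hairpin_db[0]
        host = random_transcript(rng, "host", 300)
        # ~15% divergence: below the 90% identity rule
        seq = plant_segment(rng, host.seq, hairpin.seq, 100, 12)
        assert annotate_premirnas([Transcript("host", seq)], [hairpin]) == []


class TestTargetPrediction:
    MATURE = "TGGAGAAGCAGGGCACGTGCA"  # 21 nt

    def test_perfect_site_scores_zero(self):
        rng = np.random.default_rng(5)
        host = random_transcript(rng, "t", 300)
        site = reverse_complement(self.MATURE)
        seq = host.seq[:100] + site + host.seq[100 + len(site):]
        hits = predict_targets(self.MATURE, "mirX", [Transcript("t", seq)])
        assert len(hits) == 1 and hits[0].expectation == 0.0

    def test_gu_in_seed_costs_one(self):
        # miRNA position 5 (seed): G opposite T on the target is a wobble
        mature = self.MATURE
        site = list(reverse_complement(mature))
        L = len(mature)
        assert mature[4] == "G"
        site[L - 5] = "T"  # target base facing position 5
        e = site_expectation(mature, "".join(site))
        assert e == pytest.approx(1.0)  # 0.5 wobble x 2.0 seed multiplier

    def test_mature_length_validated(self):
        with pytest.raises(ValueError):
            predict_targets("ACGT", "m", [])

    def test_planted_sites_recovered_and_controls_clean(self):
        transcripts, with_site = generate_target_set(self.MATURE, 50, 50, seed=6)
        hits = predict_targets(self.MATURE, "mirX", transcripts)
        found = {h.target_id for h in hits}
        assert found >= with_site
        assert not found - with_site  # no hits among the 50 controls

    def test_expectation_monotone_under_added_mismatch(self):
        rng = np.random.default_rng(7)
        site = reverse_complement(self.MATURE)
        base = site_expectation(self.MATURE, site)
        for pos in range(len(site)):
            for b in "ACGT":
                if b == site[pos]:
                    continue
                perturbed = site[:pos] + b + site[pos + 1:]
                assert site_expectation(self.MATURE, perturbed) >= base


class TestRegulation:
    def hits(self, n_up, n_down):
        mk = lambda i, d: TargetHit("mirX", f"t{i}", 1.0, 0, 21, d)
        return [mk(i, "up") for i in range(n_up)] + [mk(100 + i, "down") for i in range(n_down)]

    def test_down_mirna_with_mostly_up_targets_is_positive_regulator(self):
        summary = regulation_summary("down", self.hits(6, 4))
        assert summary.pct_up == pytest.approx(60.0)
        assert summary.pattern == "positive-regulator"

    def test_up_mirna_with_mostly_down_targets_is_negative_regulator(self):
        summary = regulation_summary("up", self.hits(2, 3))
        assert summary.pct_up == pytest.approx(40.0)
        assert summary.pattern == "negative-regulator"

    def test_no_directed_targets_is_an_error(self):
        with pytest.raises(ValueError):
            regulation_summary("down", [TargetHit("m", "t", 1.0, 0, 21, "ns")])
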