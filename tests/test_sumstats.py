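"""Summary-statistics I/O, instrument selection, exclusions and harmonisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate import (
    VariantAssociation,
    apply_exclusions,
    f_statistics,
    harmonize_multi,
    harmonize_pair,
    read_sumstats,
    select_instruments,
    write_sumstats,
)
from mrmediate.exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    RowError,
)


class TestVariantAssociation:
    def test_alleles_uppercased_and_validated(self):
        a = VariantAssociation("rs1", "a", "g", 0.1, 0.01, 1e-9)
        assert (a.effect_allele, a.other_allele) == ("A", "G")
        assert not a.is_palindromic
        assert VariantAssociation("rs2", "A", "T", 0.1, 0.01, 1e-9).is_palindromic

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"effect_allele": "A", "other_allele": "A"},
            {"se": 0.0},
            {"se": -1.0},
            {"pval": 0.0},
            {"pval": 1.5},
            {"eaf": 0.0},
            {"eaf": 1.0},
            {"effect_allele": "N"},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs, mk_assoc):
        with pytest.raises(RowError):
            mk_assoc(**kwargs)


class TestReadWrite:
    def _write(self, tmp_path, text, name="ss.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_well_formed_rows_round_trip(self, tmp_path, mk_assoc):
        recs = [
            mk_assoc("rs1", "A", "G", 0.1, 0.01, 1e-9, chrom="1", pos=100, eaf=0.2, n=1000),
            mk_assoc("rs2", "C", "T", -0.05, 0.02, 0.5, chrom="2", pos=200, eaf=0.4, n=1000),
            mk_assoc("rs3", "G", "C", 0.0, 0.01, 1.0, eaf=0.45),
        ]
        path = tmp_path / "out.tsv"
        write_sumstats(recs, path)
        back = read_sumstats(path)
        assert back == recs

    def test_extra_unmapped_columns_ignored(self, tmp_path):
        path = self._write(
            tmp_path,
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\tinfo_score\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-9\t0.99\n",
        )
        recs = read_sumstats(path)
        assert len(recs) == 1 and recs[0].snp_id == "rs1"

    def test_zero_se_row_error_names_row(self, tmp_path):
        path = self._write(
            tmp_path,
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-9\nrs2\tC\tT\t0.1\t0\t1e-9\n",
        )
        with pytest.raises(RowError, match="row 1"):
            read_sumstats(path)

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = self._write(tmp_path, "snp\teffect_allele\tbeta\tse\tpval\nrs1\tA\t0.1\t0.01\t1e-9\n")
        with pytest.raises(ConfigurationError, match="other_allele"):
            read_sumstats(path)

    def test_unparsable_numeric_names_row(self, tmp_path):
        path = self._write(
            tmp_path,
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\tnot_a_number\t0.01\t1e-9\n",
        )
        with pytest.raises(RowError, match="row 0"):
            read_sumstats(path)

    def test_column_remapping(self, tmp_path):
        path = self._write(
            tmp_path,
            "rsid\tEA\tOA\tb\tstderr\tp\nrs9\tA\tC\t0.2\t0.05\t1e-10\n",
        )
        recs = read_sumstats(
            path,
            column_map={
                "snp_id": "rsid", "effect_allele": "EA", "other_allele": "OA",
                "beta": "b", "se": "stderr", "pval": "p",
            },
        )
        assert recs[0].snp_id == "rs9" and recs[0].beta == 0.2


class TestSelectInstruments:
    def test_threshold_filters(self, mk_assoc):
        assocs = [mk_assoc("rs1", pval=1e-9), mk_assoc("rs2", pval=0.5)]
        assert [a.snp_id for a in select_instruments(assocs, 5e-8)] == ["rs1"]

    def test_greedy_ld_keeps_smaller_p(self, mk_assoc):
        assocs = [mk_assoc("rs1", pval=1e-9), mk_assoc("rs2", pval=1e-10)]
        ld = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"]
        )
        kept = select_instruments(assocs, 5e-8, ld=ld, r2_max=0.001)
        assert [a.snp_id for a in kept] == ["rs2"]

    def test_no_passing_snp_is_empty_instrument_error(self, mk_assoc):
        with pytest.raises(EmptyInstrumentError):
            select_instruments([mk_assoc(pval=0.5)], 5e-8)

    def test_distance_pruning_closed_window(self, mk_assoc):
        assocs = [
            mk_assoc("rs1", pval=1e-12, chrom="1", pos=1_000_000),
            mk_assoc("rs2", pval=1e-9, chrom="1", pos=2_000_000),  # exactly 1 Mb: dropped
            mk_assoc("rs3", pval=1e-9, chrom="1", pos=2_000_001),
            mk_assoc("rs4", pval=1e-9, chrom="2", pos=1_000_000),
        ]
        kept = {a.snp_id for a in select_instruments(assocs, 5e-8, window_bp=1_000_000)}
        assert kept == {"rs1", "rs3", "rs4"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_and_order_invariance(self, seed, mk_assoc):
        rng = np.random.default_rng(seed)
        n = 10
        ids = [f"rs{i}" for i in range(n)]
        pvals = rng.uniform(1e-12, 1e-8, n)
        assocs = [mk_assoc(ids[i], pval=pvals[i]) for i in range(n)]
        r2 = rng.uniform(0, 0.1, (n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = pd.DataFrame(r2, index=ids, columns=ids)
        r2_max = 0.02
        kept = select_instruments(assocs, 5e-8, ld=ld, r2_max=r2_max)
        kept_ids = [a.snp_id for a in kept]
        # every retained pair independent
        for i, a in enumerate(kept_ids):
            for b in kept_ids[i + 1:]:
                assert ld.at[a, b] < r2_max
        # every dropped SNP conflicts with a retained SNP of smaller p
        pmap = dict(zip(ids, pvals))
        for a in set(ids) - set(kept_ids):
            assert any(
                ld.at[a, b] >= r2_max and pmap[b] <= pmap[a] for b in kept_ids
            )
        shuffled = list(assocs)
        rng.shuffle(shuffled)
        assert [a.snp_id for a in select_instruments(shuffled, 5e-8, ld=ld, r2_max=r2_max)] == kept_ids


class TestApplyExclusions:
    def test_ambiguous_palindrome_dropped(self, mk_assoc):
        a = mk_assoc("rs1", "A", "T", eaf=0.50)
        retained, rep = apply_exclusions([a], outcome_ids={"rs1"})
        assert retained == [] and rep.n_palindromic_dropped == 1

    def test_resolvable_palindrome_retained(self, mk_assoc):
        a = mk_assoc("rs1", "A", "T", eaf=0.10)
        retained, rep = apply_exclusions([a], outcome_ids={"rs1"})
        assert retained == [a] and rep.n_retained == 1

    def test_palindrome_with_missing_eaf_dropped(self, mk_assoc):
        a = mk_assoc("rs1", "C", "G", eaf=None)
        retained, rep = apply_exclusions([a], outcome_ids={"rs1"})
        assert retained == [] and rep.n_palindromic_dropped == 1

    def test_counts_reconcile(self, mk_assoc):
        assocs = [
            mk_assoc("rs1"), mk_assoc("rs2"), mk_assoc("rs3"),
            mk_assoc("rs4"), mk_assoc("rs5"),
        ]
        retained, rep = apply_exclusions(
            assocs, blacklist={"rs1"}, outcome_ids={"rs1", "rs2", "rs3", "rs4"}
        )
        assert rep.n_blacklisted == 1 and rep.n_missing_in_outcome == 1
        assert rep.n_retained == 3 == len(retained)

    def test_blacklist_takes_precedence_over_palindrome(self, mk_assoc):
        a = mk_assoc("rs1", "A", "T", eaf=0.5)
        _, rep = apply_exclusions([a], blacklist={"rs1"}, outcome_ids={"rs1"})
        assert rep.n_blacklisted == 1 and rep.n_palindromic_dropped == 0

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=0,
            max_size=30,
        )
    )
    def test_report_always_reconciles(self, spec):
        assocs, blacklist, outcome_ids = [], set(), set()
        for i, (blk, present, palin) in enumerate(spec):
            snp = f"rs{i}"
            assocs.append(
                VariantAssociation(
                    snp, "A", "T" if palin else "G", 0.1, 0.01, 1e-9, eaf=0.5 if palin else 0.3
                )
            )
            if blk:
                blacklist.add(snp)
            if present:
                outcome_ids.add(snp)
        retained, rep = apply_exclusions(assocs, blacklist, outcome_ids)
        drops = (rep.n_blacklisted + rep.n_missing_in_outcome
                 + rep.n_palindromic_dropped + rep.n_outlier_dropped)
        assert rep.n_input == len(assocs)
        assert rep.n_retained == len(retained) == rep.n_input - drops


class TestHarmonizePair:
    def test_same_alleles_copied(self, mk_assoc):
        h = harmonize_pair(
            [mk_assoc("rs1", "A", "G", beta=0.1)], [mk_assoc("rs1", "A", "G", beta=0.05)]
        )
        assert h.by[0] == 0.05 and h.provenance_flags["rs1"] == "ok"

    def test_swapped_alleles_negate_outcome(self, mk_assoc):
        h = harmonize_pair(
            [mk_assoc("rs1", "A", "G", beta=0.1)], [mk_assoc("rs1", "G", "A", beta=0.05)]
        )
        assert h.by[0] == -0.05 and h.provenance_flags["rs1"] == "flipped"

    def test_strand_complement_resolved(self, mk_assoc):
        # T/C is the reverse-strand reading of A/G
        h = harmonize_pair(
            [mk_assoc("rs1", "A", "G", beta=0.1)], [mk_assoc("rs1", "T", "C", beta=0.05)]
        )
        assert h.by[0] == 0.05 and h.provenance_flags["rs1"] == "strand_complement"
        h2 = harmonize_pair(
            [mk_assoc("rs1", "A", "G", beta=0.1)], [mk_assoc("rs1", "C", "T", beta=0.05)]
        )
        assert h2.by[0] == -0.05

    def test_palindrome_resolved_by_frequency(self, mk_assoc):
        exp = [mk_assoc("rs1", "A", "T", beta=0.1, eaf=0.1)]
        concordant = harmonize_pair(exp, [mk_assoc("rs1", "A", "T", beta=0.05, eaf=0.12)])
        assert concordant.by[0] == 0.05
        discordant = harmonize_pair(exp, [mk_assoc("rs1", "A", "T", beta=0.05, eaf=0.88)])
        assert discordant.by[0] == -0.05
        assert discordant.provenance_flags["rs1"] == "palindromic_flipped"

    def test_ambiguous_palindrome_dropped_not_error(self, mk_assoc):
        exp = [
            mk_assoc("rs1", "A", "T", eaf=0.5),
            mk_assoc("rs2", "A", "G", beta=0.2),
        ]
        out = [
            mk_assoc("rs1", "A", "T", eaf=0.5),
            mk_assoc("rs2", "A", "G", beta=0.1),
        ]
        h = harmonize_pair(exp, out)
        assert h.snp_ids == ["rs2"] and h.dropped["rs1"] == "palindromic_ambiguous"

    def test_irreconcilable_alleles_dropped_with_flag(self, mk_assoc):
        exp = [mk_assoc("rs1", "A", "G"), mk_assoc("rs2", "A", "G")]
        out = [mk_assoc("rs1", "A", "C"), mk_assoc("rs2", "A", "G")]
        h = harmonize_pair(exp, out)
        assert h.snp_ids == ["rs2"] and h.dropped["rs1"] == "incompatible_alleles"

    def test_involution(self, mk_assoc):
        exp = [
            mk_assoc("rs1", "A", "G", beta=0.1, eaf=0.2),
            mk_assoc("rs2", "C", "T", beta=-0.2, eaf=0.7),
            mk_assoc("rs3", "A", "T", beta=0.15, eaf=0.1),
        ]
        out = [
            mk_assoc("rs1", "G", "A", beta=0.05, eaf=0.8),
            mk_assoc("rs2", "C", "T", beta=0.02, eaf=0.7),
            mk_assoc("rs3", "T", "A", beta=-0.03, eaf=0.9),
        ]
        h1 = harmonize_pair(exp, out)
        h2 = harmonize_pair(h1.exposure_associations(), h1.outcome_associations())
        assert h2.snp_ids == h1.snp_ids
        np.testing.assert_allclose(h2.bx, h1.bx)
        np.testing.assert_allclose(h2.by, h1.by)
        assert all(f in ("ok", "palindromic") for f in h2.provenance_flags.values())

    def test_sign_coherence_under_exposure_relabelling(self, mk_assoc):
        """Negating exposure betas and swapping allele labels flips the
        reference allele: both aligned effect vectors negate, so every
        ratio-based estimate is unchanged."""
        exp = [
            mk_assoc("rs1", "A", "G", beta=0.1, eaf=0.2),
            mk_assoc("rs2", "C", "T", beta=-0.2, eaf=0.7),
        ]
        out = [
            mk_assoc("rs1", "G", "A", beta=0.05, eaf=0.8),
            mk_assoc("rs2", "C", "T", beta=0.02, eaf=0.7),
        ]
        flipped_exp = [
            mk_assoc(a.snp_id, a.other_allele, a.effect_allele, beta=-a.beta, eaf=1 - a.eaf)
            for a in exp
        ]
        h1 = harmonize_pair(exp, out)
        h2 = harmonize_pair(flipped_exp, out)
        np.testing.assert_allclose(h2.bx, -h1.bx)
        np.testing.assert_allclose(h2.by, -h1.by)


class TestHarmonizeMulti:
    def _study(self, mk_assoc, ids, beta=0.1):
        return [mk_assoc(i, "A", "G", beta=beta) for i in ids]

    def test_disjoint_union(self, mk_assoc):
        ids_x, ids_m = ["rs1", "rs2", "rs3"], ["rs4", "rs5"]
        every = ids_x + ids_m
        h = harmonize_multi(
            self._study(mk_assoc, every),
            self._study(mk_assoc, every, 0.2),
            self._study(mk_assoc, every, 0.05),
            (self._study(mk_assoc, ids_x), self._study(mk_assoc, ids_m)),
        )
        assert h.k == 2 and h.n_snp == 5

    def test_overlapping_snp_deduplicated(self, mk_assoc):
        every = ["rs1", "rs2"]
        h = harmonize_multi(
            self._study(mk_assoc, every),
            self._study(mk_assoc, every),
            self._study(mk_assoc, every),
            (self._study(mk_assoc, ["rs1", "rs2"]), self._study(mk_assoc, ["rs2"])),
        )
        assert h.snp_ids == ["rs1", "rs2"]

    def test_missing_in_outcome_dropped_and_counted(self, mk_assoc):
        every = ["rs1", "rs2", "rs3"]
        h = harmonize_multi(
            self._study(mk_assoc, every),
            self._study(mk_assoc, every),
            self._study(mk_assoc, ["rs1", "rs2"]),
            (self._study(mk_assoc, every), []),
        )
        assert h.n_snp == 2 and h.dropped["rs3"] == "missing_in_outcome"

    def test_empty_union_is_error(self, mk_assoc):
        with pytest.raises(EmptyInstrumentError):
            harmonize_multi([], [], [], ([], []))


class TestFStatistics:
    def test_values_and_mean(self):
        from mrmediate import HarmonizedSet

        h = HarmonizedSet.from_arrays([0.1, 0.05, 0.0], [0.01, 0.01, 0.01],
                                      [0, 0, 0.0], [1, 1, 1.0])
        f, fbar = f_statistics(h)
        np.testing.assert_allclose(f, [100.0, 25.0, 0.0])
        assert fbar == pytest.approx(f.mean())
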