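"""Filter cascade operations, audit arithmetic and cascade-level properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aplnet.calls import SamplePair, VariantCall
from aplnet.filtering import (
    STAGE_LABELS,
    FilterAudit,
    FilterConfig,
    UnmatchedModeError,
    apply_site_filters,
    classify_and_filter_consequence,
    deleterious_filter,
    germline_heuristic,
    run_cascade,
    subtract_matched_remission,
    ti_tv_ratio,
    to_mutation_matrix,
)
from aplnet.simulate import generate_unmatched_calls, generate_variant_fixtures

from test_calls import make_call


class TestRemissionSubtraction:
    def test_shared_variants_removed(self):
        diagnosis = [make_call(pos=100 + i) for i in range(10)]
        remission = [
            VariantCall(chrom="1", pos=c.pos, ref=c.ref, alt=c.alt,
                        depth=60, alt_depth=27)
            for c in diagnosis[:3]
        ]
        pair = SamplePair("P1", diagnosis, remission)
        retained = subtract_matched_remission(pair)
        assert retained == diagnosis[3:]

    def test_remission_record_without_alt_support_counts_as_absent(self):
        call = make_call(pos=100)
        remission = [VariantCall(chrom="1", pos=100, ref="C", alt="T",
                                 depth=40, alt_depth=0)]
        pair = SamplePair("P1", [call], remission)
        assert subtract_matched_remission(pair) == [call]

    def test_unmatched_pair_raises_directing_to_heuristic(self):
        pair = SamplePair("P1", [make_call()], remission=None)
        with pytest.raises(UnmatchedModeError, match="germline_heuristic"):
            subtract_matched_remission(pair)


class TestGermlineHeuristic:
    def test_population_frequency_cutoff(self):
        common = make_call(pop_freq=0.05)
        rare = make_call(pos=101, pop_freq=0.001)
        assert germline_heuristic([common, rare], max_pop_freq=0.01) == [rare]

    @pytest.mark.parametrize("alt_depth,kept", [(30, False), (18, True)])
    def test_heterozygous_vaf_band(self, alt_depth, kept):
        call = make_call(depth=60, alt_depth=alt_depth, pop_freq=None)
        out = germline_heuristic([call], germline_vaf_bands=[(0.45, 0.55)])
        assert (call in out) == kept

    def test_empty_input_gives_empty_output(self):
        assert germline_heuristic([]) == []

    def test_planted_germline_mostly_removed_in_simulation(self):
        """>=90% of planted germline variants are removed over 200
        simulated unmatched patients (population-catalogue + VAF bands)."""
        calls, germline_keys = generate_unmatched_calls(n_patients=200, rng_seed=5)
        planted = removed = 0
        for patient, patient_calls in calls.items():
            kept_keys = {
                (c.chrom, c.pos, c.ref, c.alt)
                for c in germline_heuristic(patient_calls)
            }
            planted += len(germline_keys[patient])
            removed += len(germline_keys[patient] - kept_keys)
        assert removed / planted >= 0.90


class TestSiteFilters:
    @pytest.mark.parametrize("depth,kept", [(9, False), (10, True)])
    def test_depth_threshold_is_inclusive(self, depth, kept):
        call = make_call(depth=depth, alt_depth=min(depth, 5))
        assert (call in apply_site_filters([call], min_depth=10)) == kept

    def test_vacuous_thresholds_keep_everything(self):
        calls = [make_call(pos=p) for p in range(1, 20)]
        assert apply_site_filters(calls, 0, 0.0, 1.0, 0.0) == calls

    def test_survivors_match_predicate_by_predicate_rescan(self, rng):
        calls = [
            make_call(
                pos=int(p),
                depth=int(d),
                alt_depth=int(rng.integers(0, d + 1)),
                qual=float(q),
                strand_bias=float(s),
            )
            for p, d, q, s in zip(
                rng.integers(1, 10**6, 1000),
                rng.integers(0, 120, 1000),
                rng.uniform(0, 100, 1000),
                rng.uniform(0, 1, 1000),
            )
        ]
        kept = apply_site_filters(calls, min_depth=10, min_qual=30,
                                  max_strand_bias=0.9, min_vaf=0.05)
        oracle = [c for c in calls if c.depth >= 10]
        oracle = [c for c in oracle if c.qual >= 30]
        oracle = [c for c in oracle if c.strand_bias <= 0.9]
        oracle = [c for c in oracle if c.vaf >= 0.05]
        assert kept == oracle


class TestConsequenceFilters:
    def test_synonymous_removed_at_coding_stage(self):
        call = make_call(consequence="synonymous")
        assert classify_and_filter_consequence([call]) == []

    def test_truncating_consequence_overrides_missing_flag(self):
        call = make_call(consequence="stop_gain", deleterious=False)
        assert deleterious_filter([call]) == [call]

    def test_unknown_keep_label_is_configuration_error(self):
        with pytest.raises(ValueError, match="nonsense"):
            classify_and_filter_consequence([make_call()], keep={"nonsense"})

    def test_extended_cohort_composition_retains_218_of_219(self):
        """219 calls: 192 nonsynonymous + 3 frameshift + 14 stop gain +
        9 splice site + 1 ncRNA; the coding keep-set drops only the ncRNA."""
        composition = (
            ["nonsynonymous"] * 192 + ["frameshift"] * 3 + ["stop_gain"] * 14
            + ["splice_site"] * 9 + ["ncRNA"] * 1
        )
        calls = [make_call(pos=i + 1, consequence=c)
                 for i, c in enumerate(composition)]
        assert len(classify_and_filter_consequence(calls)) == 218


class TestTiTv:
    def test_direct_count(self):
        calls = [make_call(ref=r, alt=a, pos=i + 1)
                 for i, (r, a) in enumerate([("C", "T"), ("G", "A"), ("A", "G"), ("C", "A")])]
        assert ti_tv_ratio(calls) == 3.0

    def test_all_transitions_is_undefined(self):
        calls = [make_call(ref="C", alt="T")]
        assert ti_tv_ratio(calls) is None

    def test_sixtythree_to_hundred_ratio(self):
        calls = [make_call(pos=i + 1, ref="A", alt="G") for i in range(63)]
        calls += [make_call(pos=i + 100, ref="A", alt="C") for i in range(100)]
        assert ti_tv_ratio(calls) == pytest.approx(0.63)

    def test_invariant_under_strand_complementation(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        bases = ["A", "C", "G", "T"]
        calls = []
        for i in range(200):
            r, a = rng.choice(bases, size=2, replace=False)
            calls.append(make_call(pos=i + 1, ref=str(r), alt=str(a)))
        flipped = [make_call(pos=c.pos, ref=comp[c.ref], alt=comp[c.alt]) for c in calls]
        assert ti_tv_ratio(calls) == ti_tv_ratio(flipped)

    def test_indels_ignored(self):
        calls = [make_call(ref="C", alt="T"), make_call(pos=2, ref="C", alt="A"),
                 make_call(pos=3, ref="CA", alt="C")]
        assert ti_tv_ratio(calls) == 1.0


class TestCascade:
    def test_planted_stage_failures_recovered_exactly(self):
        """On generator-labelled fixtures the audit's per-stage removals
        equal the planted per-stage failure counts."""
        failures = {
            "Somatic": 3, "Absent in CR": 2, "High quality": 4,
            "Coding (SNVs+indels)": 1, "Deleterious (SNVs+indels)": 2,
            "Unknown in dbSNP": 3,
        }
        pairs, truth = generate_variant_fixtures(
            n_patients=4, somatic_per_patient=6, failures_per_stage=failures,
            rng_seed=11,
        )
        audit, retained = run_cascade(pairs, FilterConfig())
        for pair in pairs:
            row = audit.counts[pair.patient_id]
            removals = dict(zip(STAGE_LABELS[1:], (-row.diff()).iloc[1:]))
            assert removals == {k: float(v) for k, v in failures.items()}
            survivors = {
                (c.chrom, c.pos, c.ref, c.alt) for c in retained[pair.patient_id]
            }
            planted_somatic = {
                key for key, stage in truth[pair.patient_id].items() if stage is None
            }
            assert survivors == planted_somatic

    def test_cascade_deterministic(self):
        pairs, _ = generate_variant_fixtures(n_patients=3, rng_seed=2)
        audit1, ret1 = run_cascade(pairs)
        audit2, ret2 = run_cascade(pairs)
        assert audit1.counts.equals(audit2.counts)
        assert ret1 == ret2

    def test_audit_serializes_with_canonical_stage_labels(self, tmp_path):
        pairs, _ = generate_variant_fixtures(n_patients=2, rng_seed=3)
        audit, _ = run_cascade(pairs)
        path = tmp_path / "audit.tsv"
        audit.to_tsv(path)
        back = FilterAudit.from_tsv(path)
        assert tuple(back.counts.index) == STAGE_LABELS
        assert back.counts.equals(audit.counts)

    def test_mixed_cohort_requires_explicit_flag(self):
        pairs, _ = generate_variant_fixtures(n_patients=2, rng_seed=4)
        pairs[1] = SamplePair(pairs[1].patient_id, pairs[1].diagnosis, None)
        with pytest.raises(ValueError, match="allow_mixed"):
            run_cascade(pairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_audit_rows_non_increasing_on_random_cohorts(self, seed):
        pairs, _ = generate_variant_fixtures(
            n_patients=2, somatic_per_patient=3, rng_seed=seed
        )
        audit, _ = run_cascade(pairs)
        diffs = audit.counts.diff().iloc[1:].to_numpy()
        assert (diffs <= 0).all()


class TestMutationMatrixExport:
    def test_multiple_calls_in_gene_collapse_to_single_entry(self):
        calls = {"P1": [make_call(pos=100), make_call(pos=200)]}
        matrix = to_mutation_matrix(calls)
        assert matrix.df.loc["P1", "GENE1"] == 1

    def test_extra_event_sets_entry_without_calls(self):
        matrix = to_mutation_matrix({"P1": []}, extra_events={"P1": ["FLT3"]})
        assert matrix.df.loc["P1", "FLT3"] == 1

    def test_per_gene_counts_match_brute_force_tally(self, rng):
        genes = [f"G{i}" for i in range(8)]
        calls = {
            f"P{p}": [
                make_call(pos=int(rng.integers(1, 10**6)), gene=str(g))
                for g in rng.choice(genes, size=rng.integers(0, 6))
            ]
            for p in range(10)
        }
        matrix = to_mutation_matrix(calls)
        for gene in matrix.genes:
            expected = sum(
                1 for patient_calls in calls.values()
                if any(c.gene == gene for c in patient_calls)
            )
            assert matrix.carrier_counts()[gene] == expected

    def test_missing_gene_symbol_rejected(self):
        with pytest.raises(ValueError, match="no gene symbol"):
            to_mutation_matrix({"P1": [make_call(gene="")]})
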