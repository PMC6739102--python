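import numpy as np
import pytest

from maldiderep import (
    DereplicationParams,
    Dereplicator,
    PeakList,
    SpectrumDataset,
    assign_spectra,
    audit_result,
    classify_quality,
    dereplicate,
    dice_coefficient,
    match_low_quality,
    select_references,
)
from maldiderep.usf import USFMatrix
from maldiderep.synthdata import SynthConfig, synth_dataset


def peaklist(sid, mzs, snrs):
    return PeakList(sid, np.asarray(mzs, dtype=float), np.asarray(snrs, dtype=float))


class TestClassifyQuality:
    def test_green_with_five_or_more_strong_peaks(self):
        pl = peaklist("s", [4000 + 100 * k for k in range(6)], [40.0] * 6)
        qc = classify_quality(pl)
        assert qc.quality_class == "green" and qc.n_strong_peaks == 6

    def test_orange_with_one_to_four_strong_peaks(self):
        mzs = [4000 + 100 * k for k in range(13)]
        snrs = [31, 31, 35] + [10] * 10
        qc = classify_quality(peaklist("s", mzs, snrs))
        assert qc.quality_class == "orange" and qc.n_strong_peaks == 3

    def test_red_with_no_strong_peaks(self):
        qc = classify_quality(peaklist("s", [4000, 4100], [30.0, 12.0]))
        assert qc.quality_class == "red" and qc.n_strong_peaks == 0

    def test_boundary_five_peaks_just_above_cutoff(self):
        pl = peaklist("s", [4000 + 100 * k for k in range(5)], [30.5] * 5)
        assert classify_quality(pl).quality_class == "green"

    def test_snr_exactly_30_is_not_strong(self):
        pl = peaklist("s", [4000 + 100 * k for k in range(5)], [30.0] * 5)
        assert classify_quality(pl).quality_class == "red"


def usf(ids, counts):
    return USFMatrix(ids=list(ids), counts=np.asarray(counts))


class TestSelectReferences:
    def test_redundant_pair_one_reference(self):
        refs = select_references(usf("ab", [[0, 0], [0, 0]]))
        assert len(refs) == 1

    def test_all_distinct_all_references(self):
        refs = select_references(usf("abc", [[0, 1, 2], [3, 0, 1], [2, 2, 0]]))
        assert sorted(refs) == ["a", "b", "c"]

    def test_redundant_pair_plus_distinct(self):
        # a<->b redundant both ways; c distinct from both
        m = usf("abc", [[0, 0, 2], [0, 0, 3], [1, 1, 0]])
        refs = select_references(m)
        # b has the higher row sum, so it is evaluated (and selected) first
        assert refs == ["b", "c"]

    def test_sort_is_by_descending_row_sum_then_id(self):
        m = usf("ab", [[0, 5], [5, 0]])
        assert select_references(m) == ["a", "b"]

    def test_preexisting_prepended_and_unconditional(self):
        m = usf("abc", [[0, 0, 2], [0, 0, 3], [1, 1, 0]])
        refs = select_references(m, preexisting=["a"])
        assert refs[0] == "a"
        assert "b" not in refs  # b is redundant with the forced reference a

    def test_unknown_preexisting_id_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            select_references(usf("ab", [[0, 1], [1, 0]]), preexisting=["ghost"])

    def test_compare_to_references_mode(self):
        # intransitive structure: b redundant with a, c redundant with b only
        m = usf("abc", [[0, 0, 1], [0, 0, 0], [1, 0, 0]])
        lenient = select_references(m, compare_to="references")
        literal = select_references(m, compare_to="evaluated")
        assert set(lenient) <= set(literal) or len(lenient) <= len(literal)


class TestAssignSpectra:
    def test_identical_pair(self):
        m = usf("ab", [[0, 0], [0, 0]])
        refs = select_references(m)
        assignments = assign_spectra(m, refs)
        assert set(assignments.values()) == set(refs)

    def test_lowest_index_reference_wins(self):
        # s has zero USFs against refs r2 and r3; r1 earlier but nonzero
        m = usf(
            ["r1", "r2", "r3", "s"],
            [
                [0, 1, 1, 1],
                [1, 0, 1, 1],
                [1, 1, 0, 1],
                [2, 0, 0, 0],
            ],
        )
        assignments = assign_spectra(m, ["r1", "r2", "r3"])
        assert assignments["s"] == "r2"

    def test_all_distinct_only_self_assignments(self):
        m = usf("abc", [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        refs = select_references(m)
        assignments = assign_spectra(m, refs)
        assert assignments == {r: r for r in refs}

    def test_inconsistent_selection_raises(self):
        m = usf("ab", [[0, 1], [1, 0]])
        with pytest.raises(RuntimeError, match="inconsistent"):
            assign_spectra(m, ["a"])  # b has a USF against the only reference

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            assign_spectra(usf("a", [[0]]), [])


class TestDiceCoefficient:
    def test_identical_lists(self):
        pl = peaklist("a", [4000, 5000, 6000], [10] * 3)
        assert dice_coefficient(pl, pl, 700.0) == 1.0

    def test_disjoint_lists(self):
        a = peaklist("a", [4000, 5000], [10, 10])
        b = peaklist("b", [6000, 7000], [10, 10])
        assert dice_coefficient(a, b, 700.0) == 0.0

    def test_partial_overlap(self):
        a = peaklist("a", [4000, 5000, 6000, 9000], [10] * 4)
        b = peaklist("b", [4000.5, 5000.5, 6000.5, 7000, 7500, 8000], [10] * 6)
        assert dice_coefficient(a, b, 700.0) == pytest.approx(0.6)

    def test_both_empty_defined_zero(self):
        e = peaklist("e", [], [])
        assert dice_coefficient(e, e, 700.0) == 0.0


class TestMatchLowQuality:
    @pytest.fixture
    def rescue_dataset(self, make_spectrum, make_dataset):
        ref_peaks = [(5000, 100), (6000, 90), (6500, 80), (7000, 70), (7500, 60)]
        ref2_peaks = [(4400, 100), (4800, 90), (5600, 80), (6200, 70), (6800, 60)]
        records = {
            "ref1": make_spectrum("ref1", ref_peaks),
            "ref2": make_spectrum("ref2", ref2_peaks),
        }
        return make_dataset(records)

    def test_orange_matched_when_dice_exceeds_threshold(self, rescue_dataset):
        orange = peaklist("o", [5000.5, 6000.5, 6500.5, 7000.5, 7500.5], [31, 20, 20, 10, 10])
        rescue_dataset.records["o"] = (rescue_dataset.records["ref1"][0], orange)
        hits = match_low_quality(["o"], ["ref1", "ref2"], rescue_dataset)
        assert [r for r, _ in hits["o"]] == ["ref1"]
        assert hits["o"][0][1] == pytest.approx(1.0)

    def test_red_empty_list_matches_nothing(self, rescue_dataset):
        red = peaklist("r", [], [])
        rescue_dataset.records["r"] = (rescue_dataset.records["ref1"][0], red)
        hits = match_low_quality(["r"], ["ref1", "ref2"], rescue_dataset)
        assert hits["r"] == ()

    def test_multiple_references_all_recorded(self, make_spectrum, make_dataset):
        shared = [(5000, 100), (6000, 90), (6500, 80), (7000, 70), (7500, 60)]
        ds = make_dataset(
            {
                "ref1": make_spectrum("ref1", shared),
                "ref2": make_spectrum("ref2", shared),
            }
        )
        orange = peaklist("o", [m for m, _ in shared], [31, 10, 10, 10, 10])
        ds.records["o"] = (ds.records["ref1"][0], orange)
        hits = match_low_quality(["o"], ["ref1", "ref2"], ds)
        assert [r for r, _ in hits["o"]] == ["ref1", "ref2"]


class TestDereplicate:
    def test_mutually_distinct_taxa_become_singleton_oius(self, make_spectrum, make_dataset):
        layouts = {
            "a": [(4400, 90), (5000, 100), (6100, 70), (7000, 80), (7700, 60)],
            "b": [(4600, 90), (5300, 100), (6300, 70), (7200, 80), (7900, 60)],
            "c": [(4800, 90), (5600, 100), (6500, 70), (7400, 80), (7950, 60)],
        }
        ds = make_dataset({sid: make_spectrum(sid, pk) for sid, pk in layouts.items()})
        res = dereplicate(ds)
        assert sorted(res.references) == ["a", "b", "c"]
        assert all(len(m) == 1 for m in res.oius.values())

    def test_replicated_taxa_recovered(self):
        cfg = SynthConfig(n_taxa=4, replicates_per_taxon=3, seed=11)
        ds, truth = synth_dataset(cfg)
        res = dereplicate(ds)
        assert len(res.references) == 4
        for members in res.oius.values():
            assert len({truth[m] for m in members}) == 1

    def test_no_green_spectra_is_an_error(self, make_dataset, make_spectrum):
        raw, _ = make_spectrum("w", [(5000, 10)])
        weak = PeakList("w", np.array([5000.0]), np.array([10.0]))
        with pytest.raises(ValueError, match="quality"):
            dereplicate(make_dataset({"w": (raw, weak)}))

    def test_permutation_invariance(self):
        cfg = SynthConfig(n_taxa=3, replicates_per_taxon=2, seed=5)
        ds, _ = synth_dataset(cfg)
        res1 = dereplicate(ds)
        shuffled = SpectrumDataset(
            records=dict(reversed(list(ds.records.items()))),
            metadata=ds.metadata,
        )
        res2 = dereplicate(shuffled)
        assert res1.references == res2.references
        assert res1.assignments == res2.assignments

    def test_idempotence_on_selected_references(self):
        cfg = SynthConfig(n_taxa=4, replicates_per_taxon=3, seed=7)
        ds, _ = synth_dataset(cfg)
        res = dereplicate(ds)
        refs_only = SpectrumDataset(
            records={sid: ds.records[sid] for sid in res.references}
        )
        res2 = dereplicate(refs_only)
        assert sorted(res2.references) == sorted(res.references)

    def test_incremental_run_reproduces_partition(self):
        cfg = SynthConfig(n_taxa=4, replicates_per_taxon=3, seed=9)
        ds, _ = synth_dataset(cfg)
        res = dereplicate(ds)
        incremental = SpectrumDataset(
            records=ds.records, metadata=ds.metadata, reference_ids=res.references
        )
        res2 = dereplicate(incremental)
        assert res2.references == res.references
        assert {r: set(m) for r, m in res2.oius.items()} == {
            r: set(m) for r, m in res.oius.items()
        }

    def test_audit_passes_on_every_run(self):
        for seed in (1, 2):
            ds, _ = synth_dataset(SynthConfig(n_taxa=3, replicates_per_taxon=3, seed=seed))
            res = dereplicate(ds)
            audit_result(res, res.usf_matrix)  # raises on contract violation


class TestDereplicatorEstimator:
    def test_fit_sets_attributes_and_labels(self):
        ds, truth = synth_dataset(SynthConfig(n_taxa=3, replicates_per_taxon=2, seed=3,
                                              n_low_quality=1))
        est = Dereplicator()
        labels = est.fit_predict(ds)
        assert len(est.references_) == 3
        assert labels.shape == (len(ds),)
        low = [k for k, sid in enumerate(ds.ids) if sid.startswith("lowq")]
        assert all(labels[k] == -1 for k in low)
        green = [k for k in range(len(ds)) if k not in low]
        assert set(labels[green]) == {0, 1, 2}

    def test_get_set_params_round_trip_and_clone(self):
        from sklearn.base import clone

        est = Dereplicator(local_ppmc_threshold=0.2, ppm_window=500.0)
        assert est.get_params()["local_ppmc_threshold"] == 0.2
        est.set_params(ppm_window=800.0)
        twin = clone(est)
        assert twin.get_params() == est.get_params()

    def test_species_preset_matches_lowered_threshold(self):
        assert DereplicationParams.species_level().local_ppmc_threshold == 0.20
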