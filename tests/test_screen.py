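"""Panel counting, CPM, control filter, SMOTE, stacking, cross-validation."""

import numpy as np
import pytest

from neomerkit import (
    ConfigurationError,
    CountMatrix,
    FeatureFilterSpec,
    ParameterError,
    SampleMeta,
    count_panel_kmers,
    cpm_normalize,
    cross_validate,
    filter_features,
    smote_oversample,
    train_stacked_ensemble,
)
from neomerkit.kmers import revcomp
from tests.conftest import random_sequence


class TestCountPanelKmers:
    def test_single_read_examples(self):
        counts = count_panel_kmers(["ACGTGCGG"], ["GTGC", "GCGG"], k=4, canonical=False)
        assert counts.tolist() == [1, 1]

    def test_occurrence_not_presence(self):
        counts = count_panel_kmers(["GTGCGTGC"], ["GTGC"], k=4, canonical=False)
        assert counts.tolist() == [2]

    def test_no_hits(self):
        assert count_panel_kmers(["AAAAAAA"], ["GTGC"], 4, False).sum() == 0

    def test_canonical_counts_both_strands(self):
        read = "AAGTGCAA"
        counts = count_panel_kmers([read, revcomp(read)], ["GTGC"], 4, canonical=True)
        assert counts.tolist() == [2]

    def test_n_windows_skipped_and_reads_do_not_join(self):
        # GT|GC split across two reads must not count
        counts = count_panel_kmers(["AAGT", "GCAA"], ["GTGC"], 4, canonical=False)
        assert counts.sum() == 0
        counts = count_panel_kmers(["AGNTGC"], ["AGNT"[:2] + "TG"], 4, canonical=False)
        assert counts.sum() == 0

    def test_empty_panel_rejected(self):
        with pytest.raises(ParameterError):
            count_panel_kmers(["ACGT"], [], 4)

    def test_fastq_input_plain_and_gzip(self, tmp_path):
        import gzip

        for name in ("r.fastq", "r.fastq.gz"):
            p = tmp_path / name
            opener = gzip.open if name.endswith(".gz") else open
            with opener(p, "wt") as fh:
                fh.write("@r1\nACGTGCGG\n+\nIIIIIIII\n")
            counts = count_panel_kmers(p, ["GTGC"], 4, canonical=False)
            assert counts.tolist() == [1]

    def test_matches_naive_sliding_scan(self, rng):
        """Counting oracle: vectorized counter equals a per-read window scan."""
        for _ in range(30):
            k = int(rng.integers(4, 8))
            panel = sorted({random_sequence(rng, k) for _ in range(10)})
            reads = [random_sequence(rng, int(rng.integers(k, 60))) for _ in range(50)]
            for canonical_mode in (False, True):
                if canonical_mode and any(
                    revcomp(a) == b for a in panel for b in panel if a != b
                ):
                    continue  # colliding canonical pair; counter rejects these
                naive = {km: 0 for km in panel}
                lookup = {}
                for km in panel:
                    lookup[km] = km
                    if canonical_mode:
                        lookup[revcomp(km)] = km
                for read in reads:
                    for i in range(len(read) - k + 1):
                        w = read[i : i + k]
                        if w in lookup:
                            naive[lookup[w]] += 1
                got = count_panel_kmers(reads, panel, k, canonical_mode)
                assert got.tolist() == [naive[km] for km in panel]


class TestCpm:
    def test_rows_scale_to_one_million(self):
        cpm = cpm_normalize(np.array([[2, 3, 5], [1, 0, 0]]))
        assert cpm[0].tolist() == [200000.0, 300000.0, 500000.0]
        assert cpm[1, 0] == 1e6

    def test_zero_row_stays_zero(self):
        cpm = cpm_normalize(np.array([[0, 0], [3, 1]]))
        assert cpm[0].tolist() == [0.0, 0.0]
        assert cpm[1].sum() == pytest.approx(1e6, rel=1e-9)

    def test_single_feature(self):
        assert cpm_normalize(np.array([[7]]))[0, 0] == 1e6


class TestFilterFeatures:
    def test_boundary_exactly_40_percent_retained(self):
        # 2 of 5 controls exceed 20 -> 40% is not strictly greater -> retained
        counts = np.array([[0], [25], [30], [0], [10]])
        keep = filter_features(counts, np.ones(5, bool), FeatureFilterSpec(20))
        assert keep.tolist() == [True]

    def test_sixty_percent_removed(self):
        counts = np.array([[25], [30], [21], [0], [0]])
        keep = filter_features(counts, np.ones(5, bool), FeatureFilterSpec(20))
        assert keep.tolist() == [False]

    def test_threshold_is_strict(self):
        # counts exactly at the threshold never exceed it
        counts = np.array([[20], [20], [20], [20], [20]])
        keep = filter_features(counts, np.ones(5, bool), FeatureFilterSpec(20))
        assert keep.tolist() == [True]

    def test_fraction_one_is_vacuous(self):
        counts = np.array([[999], [999], [999]])
        spec = FeatureFilterSpec(20, control_fraction=1.0)
        assert filter_features(counts, np.ones(3, bool), spec).tolist() == [True]

    def test_requires_controls(self):
        with pytest.raises(ConfigurationError):
            filter_features(np.zeros((3, 2)), np.zeros(3, bool), FeatureFilterSpec(20))

    def test_only_control_rows_matter(self):
        counts = np.array([[1000, 0], [0, 0], [0, 0]])
        mask = np.array([False, True, True])  # row 0 is a case
        keep = filter_features(counts, mask, FeatureFilterSpec(20))
        assert keep.tolist() == [True, True]


class TestSmote:
    def test_balances_9_controls_against_29_cases(self, rng):
        X = rng.random((38, 6))
        y = np.r_[np.ones(29, int), np.zeros(9, int)]
        Xa, ya = smote_oversample(X, y, seed=0)
        assert (ya == 0).sum() == (ya == 1).sum() == 29
        assert np.array_equal(Xa[:38], X)  # originals preserved, synthetics appended

    def test_balanced_input_unchanged(self, rng):
        X = rng.random((10, 3))
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        Xa, ya = smote_oversample(X, y, seed=1)
        assert np.array_equal(Xa, X) and np.array_equal(ya, y)

    def test_synthetic_points_are_convex_combinations(self, rng):
        X = rng.random((20, 4))
        y = np.r_[np.ones(15, int), np.zeros(5, int)]
        Xa, ya = smote_oversample(X, y, seed=2)
        minority = X[y == 0]
        for x in Xa[20:]:
            # x = a + u (b - a) for some minority pair (a, b) and u in [0,1]
            ok = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    nz = np.abs(d) > 1e-12
                    if not nz.any():
                        continue
                    u = (x - minority[i])[nz] / d[nz]
                    if np.allclose(u, u[0], atol=1e-9) and -1e-9 <= u[0] <= 1 + 1e-9:
                        ok = True
            assert ok

    def test_determinism_and_single_minority_error(self, rng):
        X = rng.random((12, 3))
        y = np.r_[np.ones(8, int), np.zeros(4, int)]
        a = smote_oversample(X, y, seed=7)
        b = smote_oversample(X, y, seed=7)
        assert np.array_equal(a[0], b[0])
        y1 = np.r_[np.ones(11, int), [0]]
        with pytest.raises(ParameterError, match="duplicate_fallback"):
            smote_oversample(X, y1, seed=0)
        Xa, ya = smote_oversample(X, y1, seed=0, duplicate_fallback=True)
        assert (ya == 0).sum() == 11


def _matched_matrices(rng, n_case=20, n_control=10, n_feat=15, effect=6.0):
    """Synthetic matched RNA/DNA count matrices with a case-specific signal."""
    n = n_case + n_control
    samples = lambda mod: [
        SampleMeta(f"S{i:02d}", "case" if i < n_case else "control", mod)
        for i in range(n)
    ]
    mats = {}
    for mod in ("RNA", "DNA"):
        base = rng.poisson(3.0, size=(n, n_feat))
        base[:n_case, : n_feat // 2] += rng.poisson(effect, size=(n_case, n_feat // 2))
        mats[mod] = CountMatrix(mod, samples(mod), [f"K{j}" for j in range(n_feat)], base)
    return mats["RNA"], mats["DNA"]


class TestStackedEnsemble:
    def test_separable_data_perfect_training_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        rna, dna = _matched_matrices(rng, effect=50.0)
        y = rna.labels
        model = train_stacked_ensemble(rna.counts.astype(float), dna.counts.astype(float), y, seed=0)
        prob = model.predict_proba(rna.counts, dna.counts)[:, 1]
        assert roc_auc_score(y, prob) == 1.0
        assert ((prob >= 0) & (prob <= 1)).all()

    def test_refit_same_seed_reproduces_predictions(self, rng):
        rna, dna = _matched_matrices(rng)
        y = rna.labels
        p1 = train_stacked_ensemble(rna.counts, dna.counts, y, seed=3).predict_proba(
            rna.counts, dna.counts
        )
        p2 = train_stacked_ensemble(rna.counts, dna.counts, y, seed=3).predict_proba(
            rna.counts, dna.counts
        )
        assert np.array_equal(p1, p2)

    def test_constant_features_give_valid_probabilities(self, rng):
        n = 20
        samples = [
            SampleMeta(f"S{i}", "case" if i < 12 else "control", "RNA") for i in range(n)
        ]
        X = np.ones((n, 3))
        y = np.array([1] * 12 + [0] * 8)
        model = train_stacked_ensemble(X, X, y, seed=0)
        prob = model.predict_proba(X, X)
        assert ((prob >= 0) & (prob <= 1)).all()


class TestCrossValidate:
    def test_fold_arithmetic_and_stratification(self, rng):
        rna, dna = _matched_matrices(rng, n_case=29, n_control=9)
        res = cross_validate(rna, dna, folds=5, seed=0,
                             rna_filter=FeatureFilterSpec(10**6),
                             dna_filter=FeatureFilterSpec(10**6))
        y = rna.labels
        folds = np.asarray(res.fold_assignments)
        assert set(folds) == set(range(5))
        for f in range(5):
            test = folds == f
            assert test.sum() in (7, 8)
            assert len(set(y[test])) == 2  # both classes held out
        assert len(res.roc_aucs) == 5 and len(res.pr_aucs) == 5
        assert all(0 <= a <= 1 for a in res.roc_aucs + res.pr_aucs)

    def test_class_smaller_than_folds_rejected(self, rng):
        rna, dna = _matched_matrices(rng, n_case=10, n_control=4)
        with pytest.raises(ParameterError, match="folds"):
            cross_validate(rna, dna, folds=5, seed=0)

    def test_modality_mismatch_rejected(self, rng):
        rna, dna = _matched_matrices(rng)
        dna.samples[0].sample_id = "OTHER"
        with pytest.raises(ConfigurationError):
            cross_validate(rna, dna)

    def test_no_leakage_filter_uses_training_controls_only(self, rng):
        """Fold audit: the feature filter only ever sees training-fold rows."""
        rna, dna = _matched_matrices(rng, n_case=20, n_control=10)
        res = cross_validate(rna, dna, folds=5, seed=1,
                             rna_filter=FeatureFilterSpec(10**6),
                             dna_filter=FeatureFilterSpec(10**6))
        for detail in res.fold_details:
            train = set(detail["train_indices"])
            test = set(detail["test_indices"])
            controls = set(detail["filter_control_indices"])
            assert controls <= train
            assert controls.isdisjoint(test)
            assert train.isdisjoint(test)

    def test_held_out_control_cannot_trigger_filter(self, rng):
        """A feature noisy only in held-out controls survives training filters."""
        n_case, n_control = 10, 5
        n = n_case + n_control
        samples = lambda mod: [
            SampleMeta(f"S{i:02d}", "case" if i < n_case else "control", mod)
            for i in range(n)
        ]
        counts = rng.poisson(2.0, size=(n, 8))
        counts[n_case, 0] = 10_000  # one control blows up feature 0
        rna = CountMatrix("RNA", samples("RNA"), [f"K{j}" for j in range(8)], counts)
        dna = CountMatrix("DNA", samples("DNA"), [f"K{j}" for j in range(8)], counts.copy())
        res = cross_validate(rna, dna, folds=5, seed=0,
                             rna_filter=FeatureFilterSpec(100, 0.0),
                             dna_filter=FeatureFilterSpec(100, 0.0))
        # in the fold where S10 is held out, feature 0 must be retained
        fold_of_s10 = res.fold_assignments[n_case]
        detail = res.fold_details[fold_of_s10]
        assert detail["n_features_rna"] == 8
        # in every other fold it is filtered out (fraction 0.0 = any control)
        for f, d in enumerate(res.fold_details):
            if f != fold_of_s10:
                assert d["n_features_rna"] == 7


def test_count_matrix_tsv_roundtrip(tmp_path, rng):
    rna, _ = _matched_matrices(rng, n_case=4, n_control=3)
    path = tmp_path / "counts.tsv"
    rna.to_tsv(path, {"seed": 1})
    loaded = CountMatrix.from_tsv(path)
    assert loaded.modality == rna.modality
    assert loaded.features == rna.features
    assert np.array_equal(loaded.counts, rna.counts)
    assert [s.sample_id for s in loaded.samples] == [s.sample_id for s in rna.samples]
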