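import numpy as np
import pandas as pd
import pytest

import consensusvs.scoring_channels as sc
from consensusvs.chem_features import compute_fingerprints, tanimoto
from consensusvs.data_io import CompoundRecord
from consensusvs.errors import ConfigError, DuplicateIdError, EmptyInputError
from consensusvs.scoring_channels import (
    ingest_docking_scores,
    kmeans_clusters,
    parse_vina_log,
    pharmacophore_scores,
    qsar_targets,
    representatives_by_longest_smiles,
    similarity_scores,
)

ALKANOLS = ["CCO", "CCCO", "CCCCO", "CCCCCO", "CC(C)O"]
POLYAROMATICS = ["c1ccc2ccccc2c1", "c1ccc2cc3ccccc3cc2c1",
                 "c1ccc(-c2ccccc2)cc1", "c1ccc2c(c1)ccc1ccccc12"]


def _records(smiles_list, role="active", pic50=6.0):
    return [CompoundRecord(id=f"m{i}", smiles=s, role=role,
                           pic50=pic50 if role == "active" else None)
            for i, s in enumerate(smiles_list)]


class TestKmeans:
    def test_k_equal_to_count_gives_singletons(self):
        recs = _records(ALKANOLS)
        fm = compute_fingerprints(recs)
        model = kmeans_clusters(fm, k=5, seed=0)
        assert sorted(model.assignments.value_counts()) == [1] * 5

    def test_well_separated_series_never_mix(self):
        recs = _records(ALKANOLS + POLYAROMATICS)
        fm = compute_fingerprints(recs)
        model = kmeans_clusters(fm, k=3, seed=0)
        series = {r.id: ("ol" if i < len(ALKANOLS) else "ar")
                  for i, r in enumerate(recs)}
        # oracle: within/between Tanimoto confirms the two series are separable
        X = fm.values
        within = [tanimoto(X[i], X[j]) for i in range(5) for j in range(i + 1, 5)]
        between = [tanimoto(X[i], X[j]) for i in range(5) for j in range(5, 9)]
        assert min(within) > max(between)
        for label in set(model.assignments):
            members = model.members(label)
            assert len({series[m] for m in members}) == 1

    def test_same_seed_identical_assignment(self):
        recs = _records(ALKANOLS + POLYAROMATICS)
        fm = compute_fingerprints(recs)
        a = kmeans_clusters(fm, k=4, seed=9).assignments
        b = kmeans_clusters(fm, k=4, seed=9).assignments
        assert a.equals(b)

    def test_fewer_compounds_than_k_is_an_error(self):
        fm = compute_fingerprints(_records(ALKANOLS[:3]))
        with pytest.raises(EmptyInputError):
            kmeans_clusters(fm, k=4)

    def test_k_outside_range_rejected(self):
        fm = compute_fingerprints(_records(ALKANOLS))
        with pytest.raises(ConfigError):
            kmeans_clusters(fm, k=2)


class TestRepresentatives:
    def test_longest_smiles_wins(self):
        recs = _records(["CCO", "CCCCO"])
        fm = compute_fingerprints(recs + _records(POLYAROMATICS[:2], "active"))
        # build a trivial cluster model by hand
        from consensusvs.scoring_channels import ClusterModel
        model = ClusterModel(
            assignments=pd.Series([0, 0], index=["m0", "m1"]), k=3, seed=0)
        reps = representatives_by_longest_smiles(model, recs)
        assert reps == ["m1"]

    def test_one_representative_per_cluster(self):
        recs = _records(ALKANOLS + POLYAROMATICS)
        fm = compute_fingerprints(recs)
        model = kmeans_clusters(fm, k=3, seed=0)
        reps = representatives_by_longest_smiles(model, recs)
        assert len(reps) == 3
        assert len(set(reps)) == 3


class TestSimilarity:
    def test_representative_scores_one_against_itself(self):
        recs = _records(ALKANOLS)
        table = similarity_scores(recs, ["m0"])
        assert table.scores["m0"] == 1.0
        assert table.orientation == "higher_better"

    def test_disjoint_bits_score_zero(self):
        recs = _records(["C", "c1ccccc1"], role="decoy")
        table = similarity_scores(recs, ["m1"])
        assert table.scores["m0"] == 0.0

    def test_max_over_representatives_matches_brute_force(self):
        recs = _records(["CCCO", "CCO", "c1ccccc1"])
        fm = compute_fingerprints(recs)
        # oracle: direct bit-set intersection/union counting
        def brute(a, b):
            sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
            return len(sa & sb) / len(sa | sb)
        expected = max(brute(fm.values[0], fm.values[1]),
                       brute(fm.values[0], fm.values[2]))
        table = similarity_scores(recs, ["m1", "m2"])
        assert table.scores["m0"] == pytest.approx(expected)
        assert 0.0 <= table.scores.min() and table.scores.max() <= 1.0

    def test_empty_representatives_rejected(self):
        with pytest.raises(EmptyInputError):
            similarity_scores(_records(ALKANOLS), [])


class TestPharmacophore:
    def test_singleton_cluster_member_has_zero_rmse(self):
        # each molecule carries >= 3 nonzero feature families, so every
        # singleton cluster keeps its own consensus: exact feature match
        recs = _records(["Oc1ccccc1", "OCc1ccncc1", "NCc1ccccc1O",
                         "O=C(O)c1ccccc1", "NCC(=O)O"])
        fm = compute_fingerprints(recs)
        model = kmeans_clusters(fm, k=5, seed=1)  # singletons
        table = pharmacophore_scores(recs, model, min_features=3)
        assert (table.scores.abs() < 1e-12).all()
        assert table.orientation == "lower_better"

    def test_two_member_cluster_hand_arithmetic(self, monkeypatch):
        counts = {"m0": np.array([1, 1, 1, 0, 0, 0], dtype=float),
                  "m1": np.array([1, 1, 3, 0, 0, 0], dtype=float)}
        monkeypatch.setattr(sc, "feature_family_counts",
                            lambda rec: counts[rec.id])
        recs = _records(["CCO", "CCCO"])
        from consensusvs.scoring_channels import ClusterModel
        model = ClusterModel(
            assignments=pd.Series([0, 0], index=["m0", "m1"]), k=3, seed=0)
        table = pharmacophore_scores(recs, model, min_features=3)
        # consensus (1,1,2,0,0,0); member deviation 1 in one of six families
        assert table.scores["m1"] == pytest.approx(np.sqrt(1 / 6), abs=1e-9)
        assert table.scores["m0"] == pytest.approx(np.sqrt(1 / 6), abs=1e-9)

    def test_scores_invariant_to_compound_order(self):
        recs = _records(ALKANOLS + POLYAROMATICS)
        fm = compute_fingerprints(recs)
        model = kmeans_clusters(fm, k=3, seed=2)
        fwd = pharmacophore_scores(recs, model, min_features=3)
        rev = pharmacophore_scores(list(reversed(recs)), model, min_features=3)
        assert fwd.scores.sort_index().equals(rev.scores.sort_index())


class TestDockingIngestion:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "dock.csv"
        path.write_text("id,score\na,-9.1\nb,-7.2\nc,-5.0\n")
        table, orphans = ingest_docking_scores(path, known_ids=["a", "b", "c"])
        assert len(table.scores) == 3 and not orphans
        assert table.orientation == "lower_better"

    def test_vina_log_best_mode_affinity(self, tmp_path):
        log = tmp_path / "liga.log"
        log.write_text(
            "mode |   affinity | dist from best mode\n"
            "     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n"
            "-----+------------+----------+----------\n"
            "   1       -9.1      0.000      0.000\n"
            "   2       -8.6      1.902      3.001\n")
        assert parse_vina_log(log) == -9.1
        table, _ = ingest_docking_scores(tmp_path, known_ids=["liga"])
        assert table.scores["liga"] == -9.1

    def test_conflicting_duplicate_scores_raise(self, tmp_path):
        path = tmp_path / "dock.csv"
        path.write_text("id,score\na,-9.1\na,-8.0\n")
        with pytest.raises(DuplicateIdError):
            ingest_docking_scores(path)

    def test_orphans_reported(self, tmp_path):
        path = tmp_path / "dock.csv"
        path.write_text("id,score\na,-9.1\nzz,-1.0\n")
        _, orphans = ingest_docking_scores(path, known_ids=["a"])
        assert orphans == ["zz"]


class TestQsarTargets:
    def test_pic50_passthrough_and_orientation(self):
        recs = [CompoundRecord(id="a", smiles="CCO", role="active", ic50_uM=1.0)]
        table = qsar_targets(recs)
        assert table.scores["a"] == pytest.approx(6.0)
        assert table.orientation == "higher_better"

    def test_decoys_get_no_target(self):
        recs = [CompoundRecord(id="a", smiles="CCO", role="active", pic50=6.0),
                CompoundRecord(id="d", smiles="CCN", role="decoy")]
        table = qsar_targets(recs)
        assert list(table.scores.index) == ["a"]

    def test_active_without_activity_is_an_error(self):
        recs = [CompoundRecord(id="a", smiles="CCO", role="active")]
        with pytest.raises(ValueError):
            qsar_targets(recs)

    def test_row_count_matches_actives(self, small_bundle):
        table = qsar_targets(small_bundle.records)
        assert len(table.scores) == len(small_bundle.actives)
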