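import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from halobarcode import taxassign as ta
from halobarcode.exceptions import DomainError, SchemaError

GROUPS = {
    "Salicornia persica": "S. europaea complex",
    "Salicornia europea": "S. europaea complex",
    "Salicornia patula": "S. europaea complex",
    "Salicornia brachiate": "S. europaea complex",
    "Salicornia herbacea": "S. europaea complex",
    "Salicornia maritime": "S. europaea complex",
}


def hit(query="q1", species="Salicornia bigelovii", genus="Salicornia",
        family="Amaranthaceae", score=200.0, qcov=100.0, ident=99.0,
        subject=None):
    return ta.HitRecord(
        query_id=query,
        subject_id=subject or f"acc_{species.replace(' ', '_')}",
        subject_species=species,
        genus=genus,
        family=family,
        max_score=score,
        query_cover=qcov,
        identity=ident,
    )


class TestHitTableIO:
    def test_round_trip_five_rows(self, tmp_path):
        hits = [hit(query=f"q{i}") for i in range(5)]
        p = tmp_path / "hits.tsv"
        ta.write_hit_table(hits, p)
        assert ta.read_hit_table(p) == hits

    def test_identity_out_of_range(self, tmp_path):
        p = tmp_path / "hits.tsv"
        ta.write_hit_table([hit()], p)
        text = p.read_text().replace("99.0", "101")
        p.write_text(text)
        with pytest.raises(SchemaError):
            ta.read_hit_table(p)

    def test_missing_taxonomy_column(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("qseqid\tsseqid\tbitscore\nq1\ts1\t100\n")
        with pytest.raises(SchemaError, match="family"):
            ta.read_hit_table(p)

    def test_empty_table_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "hits.tsv"
        p.write_text("\t".join(ta.HIT_COLUMNS) + "\n")
        with caplog.at_level("WARNING"):
            assert ta.read_hit_table(p) == []
        assert "empty" in caplog.text


class TestWeightedScore:
    @pytest.mark.parametrize(
        "score, qcov, ident, expected",
        [
            (200.0, 100.0, 100.0, 200.0),
            (200.0, 98.0, 96.0, 204.1667),
            (0.0, 50.0, 99.0, 0.0),
        ],
    )
    def test_examples(self, score, qcov, ident, expected):
        assert ta.weighted_score(
            hit(score=score, qcov=qcov, ident=ident)
        ) == pytest.approx(expected, abs=5e-5)

    @given(
        score=st.floats(0, 1000, allow_nan=False),
        value=st.floats(1, 100, allow_nan=False),
    )
    def test_neutral_when_cover_equals_identity(self, score, value):
        h = hit(score=score, qcov=value, ident=value)
        assert ta.weighted_score(h) == pytest.approx(score)


class TestIdentityTier:
    @pytest.mark.parametrize(
        "ident, tier",
        [(96, "High"), (95, "High"), (94.99, "Medium"), (90, "Medium"),
         (89.999, "Low"), (88, "Low")],
    )
    def test_boundaries_upper_bound_wins(self, ident, tier):
        assert ta.identity_tier(ident) == tier


class TestCandidateSet:
    def test_simple_keeps_max_score_order(self):
        hits = [hit(score=s) for s in (100, 300, 200)]
        cands = ta.candidate_set(hits, "simple")
        assert [c.max_score for c in cands] == [300, 200, 100]

    def test_simple_truncates_to_ten(self):
        hits = [hit(score=i) for i in range(15)]
        assert len(ta.candidate_set(hits, "simple")) == 10

    def test_optimized_truncates_to_hundred(self):
        hits = [hit(score=1000 - i) for i in range(150)]
        assert len(ta.candidate_set(hits, "optimized")) == 100

    def test_optimized_reranks_by_weighted_score(self):
        low = hit(species="A sp", score=200, qcov=90, ident=99)  # ws ~181.8
        high = hit(species="B sp", score=195, qcov=100, ident=95)  # ws ~205.3
        cands = ta.candidate_set([low, high], "optimized")
        assert cands[0].subject_species == "B sp"

    def test_tie_break_identity_then_name(self):
        a = hit(species="Zeta sp", score=200, qcov=100, ident=100)
        b = hit(species="Alpha sp", score=200, qcov=100, ident=100)
        c = hit(species="Mid sp", score=200, qcov=99.5, ident=99.5)
        cands = ta.candidate_set([a, b, c], "optimized")
        # equal weighted scores: higher identity first, then name ascending
        assert [x.subject_species for x in cands] == [
            "Alpha sp", "Zeta sp", "Mid sp"
        ]

    def test_empty_hits_rejected(self):
        with pytest.raises(DomainError):
            ta.candidate_set([], "simple")


class TestSpeciesWithinDeviation:
    def test_single_species(self):
        cands = ta.candidate_set([hit()], "optimized")
        assert ta.species_within_deviation(cands, "optimized") == [
            "Salicornia bigelovii"
        ]

    def test_runner_up_inside_one_percent(self):
        best = hit(species="A sp", score=204.2, qcov=100, ident=100)
        close = hit(species="B sp", score=203.0, qcov=100, ident=100)
        cands = ta.candidate_set([best, close], "simple")
        assert ta.species_within_deviation(cands, "simple") == ["A sp", "B sp"]

    def test_runner_up_outside_one_percent(self):
        best = hit(species="A sp", score=204.2, qcov=100, ident=100)
        far = hit(species="B sp", score=200.0, qcov=100, ident=100)
        cands = ta.candidate_set([best, far], "simple")
        assert ta.species_within_deviation(cands, "simple") == ["A sp"]


def case(tag, hits, rank, taxon, tier=None):
    return pytest.param(hits, rank, taxon, tier, id=tag)


LADDER_CASES = [
    # rule 1: High tier, single species in deviation set
    case("high_single_species", [hit(ident=99)], "species",
         "Salicornia bigelovii", "High"),
    case("high_boundary_95", [hit(ident=95)], "species",
         "Salicornia bigelovii", "High"),
    case("high_far_runner_up",
         [hit(species="A sp", score=204.2), hit(species="B sp", score=200.0)],
         "species", "A sp", "High"),
    # rule 2: all deviation species inside the synonym complex
    case("high_synonym_group",
         [hit(species="Salicornia europea", score=200),
          hit(species="Salicornia patula", score=199.5),
          hit(species="Salicornia herbacea", score=199.0)],
         "species_group", "S. europaea complex", "High"),
    case("medium_synonym_group",
         [hit(species="Salicornia europea", score=200, ident=92),
          hit(species="Salicornia maritime", score=199.5, ident=91)],
         "species_group", "S. europaea complex", "Medium"),
    case("medium_single_grouped_species",
         [hit(species="Salicornia persica", ident=93)],
         "species_group", "S. europaea complex", "Medium"),
    # rule 3: one genus, mixed species outside any one group
    case("high_one_genus",
         [hit(species="Salicornia bigelovii", score=200),
          hit(species="Salicornia fruticosa", score=199.5)],
         "genus", "Salicornia", "High"),
    case("medium_single_ungrouped_species_degrades_to_genus",
         [hit(species="Salicornia bigelovii", ident=92)],
         "genus", "Salicornia", "Medium"),
    case("medium_one_genus",
         [hit(species="Salicornia bigelovii", ident=91, score=200),
          hit(species="Salicornia fruticosa", ident=90.5, score=199.9)],
         "genus", "Salicornia", "Medium"),
    # rule 4: one family
    case("high_two_genera_one_family",
         [hit(species="Salicornia bigelovii", genus="Salicornia", score=200),
          hit(species="Suaeda maritima", genus="Suaeda", score=199.5)],
         "family", "Amaranthaceae", "High"),
    case("medium_two_genera_one_family",
         [hit(species="Salicornia bigelovii", genus="Salicornia", ident=92,
              score=200),
          hit(species="Suaeda maritima", genus="Suaeda", ident=91,
              score=199.5)],
         "family", "Amaranthaceae", "Medium"),
    case("low_unanimous_family",
         [hit(species="Salicornia bigelovii", genus="Salicornia", ident=85,
              score=200),
          hit(species="Suaeda maritima", genus="Suaeda", ident=84,
              score=199.5)],
         "family", "Amaranthaceae", "Low"),
    case("low_single_species_still_family_only",
         [hit(ident=85)], "family", "Amaranthaceae", "Low"),
    # rule 5: unassigned
    case("low_two_families",
         [hit(species="Salicornia bigelovii", family="Amaranthaceae",
              ident=85, score=200),
          hit(species="Atriplex halimus", genus="Atriplex",
              family="Chenopodiaceae", ident=84, score=199.5)],
         "unassigned", "", "Low"),
    case("high_two_families",
         [hit(species="Salicornia bigelovii", family="Amaranthaceae",
              score=200),
          hit(species="Avicennia marina", genus="Avicennia",
              family="Acanthaceae", score=199.5)],
         "unassigned", "", "High"),
    case("medium_mixed_groups_one_genus",
         [hit(species="Salicornia europea", ident=92, score=200),
          hit(species="Salicornia bigelovii", ident=91.5, score=199.5)],
         "genus", "Salicornia", "Medium"),
    case("high_group_plus_outsider_one_genus",
         [hit(species="Salicornia europea", score=200),
          hit(species="Salicornia patula", score=199.8),
          hit(species="Salicornia bigelovii", score=199.5)],
         "genus", "Salicornia", "High"),
    case("far_decoys_ignored_in_deviation",
         [hit(species="Salicornia bigelovii", score=200),
          hit(species="Suaeda maritima", genus="Suaeda", score=150),
          hit(species="Atriplex halimus", genus="Atriplex",
              family="Chenopodiaceae", score=120)],
         "species", "Salicornia bigelovii", "High"),
    case("low_one_genus_not_genus_rank",
         [hit(species="Salicornia bigelovii", ident=80, score=200),
          hit(species="Salicornia fruticosa", ident=79, score=199.5)],
         "family", "Amaranthaceae", "Low"),
    case("medium_boundary_90",
         [hit(species="Salicornia persica", ident=90)],
         "species_group", "S. europaea complex", "Medium"),
]


class TestAssignmentLadder:
    @pytest.mark.parametrize("hits, rank, taxon, tier", LADDER_CASES)
    def test_ladder(self, hits, rank, taxon, tier):
        a = ta.assign("q1", hits, method="simple", synonym_groups=GROUPS)
        assert (a.rank, a.taxon) == (rank, taxon)
        if tier is not None:
            assert a.tier == tier

    def test_empty_hits_unassigned_zero_candidates(self):
        a = ta.assign("q1", [], method="simple")
        assert a.rank == "unassigned" and a.n_candidate_species == 0

    def test_species_rank_implies_single_candidate(self):
        for hits, rank, taxon, _ in [c.values for c in LADDER_CASES]:
            a = ta.assign("q1", hits, method="simple", synonym_groups=GROUPS)
            if a.rank == "species":
                assert a.n_candidate_species == 1

    def test_simple_and_optimized_agree_with_neutral_weights(self):
        """When <=10 hits exist and cover equals identity for every hit, the
        weighted score equals the bit score and the methods coincide."""
        hits = [
            hit(species=f"sp {i}", score=200 - i, qcov=95, ident=95)
            for i in range(8)
        ]
        a = ta.assign("q1", hits, "simple", GROUPS)
        b = ta.assign("q1", hits, "optimized", GROUPS)
        assert (a.rank, a.taxon, a.n_candidate_species) == (
            b.rank, b.taxon, b.n_candidate_species
        )


class TestConsensus:
    def asg(self, rank, taxon, genus="Salicornia", family="Amaranthaceae"):
        return ta.Assignment("q1", rank, taxon, "High", 1, "optimized",
                             genus=genus, family=family)

    def test_species_vote_projects_to_genus(self):
        members = [self.asg("genus", "Salicornia"),
                   self.asg("species", "Salicornia bigelovii")]
        c = ta.consensus_assignment(members, "q1", "core")
        assert (c.rank, c.taxon) == ("genus", "Salicornia")

    def test_majority_species(self):
        members = [self.asg("species", "Salicornia bigelovii")] * 2 + [
            self.asg("genus", "Salicornia")
        ]
        c = ta.consensus_assignment(members, "q1", "coding")
        assert (c.rank, c.taxon) == ("species", "Salicornia bigelovii")

    def test_split_species_votes_degrade_to_genus(self):
        members = [self.asg("species", "Salicornia bigelovii"),
                   self.asg("species", "Salicornia fruticosa")]
        c = ta.consensus_assignment(members, "q1", "core")
        assert (c.rank, c.taxon) == ("genus", "Salicornia")

    def test_no_consensus_is_unassigned(self):
        members = [
            self.asg("genus", "Salicornia"),
            self.asg("genus", "Suaeda", genus="Suaeda", family="X"),
        ]
        c = ta.consensus_assignment(members, "q1", "core")
        assert c.rank == "unassigned"


class TestEfficiencySummary:
    def test_all_species_level(self):
        assignments = [
            ta.Assignment(f"q{i}", "species", "X", "High", 1, "simple")
            for i in range(10)
        ]
        df = ta.summarize_efficiency({"rbcL": assignments})
        row = df.set_index("label").loc["rbcL"]
        assert row["species"] == 100.0

    def test_percentages_sum_to_100_per_label(self):
        rng = np.random.default_rng(1)
        ranks = list(ta.RANKS)
        assignments = [
            ta.Assignment(f"q{i}", rng.choice(ranks), "X", "High", 1, "simple")
            for i in range(37)
        ]
        df = ta.summarize_efficiency({"m": assignments})
        assert df[list(ta.RANKS)].sum(axis=1).iloc[0] == pytest.approx(100.0)

    def test_empty_input(self):
        assert ta.summarize_efficiency({}).empty


class TestSyntheticRecovery:
    def test_true_species_recovered_without_noise(self):
        from halobarcode import simulate_hit_table, simulate_species_sequences

        for seed in range(10):
            recs, truth = simulate_species_sequences(k=4, n_per=4, seed=seed)
            hits = simulate_hit_table(truth, score_noise_sd=0.0,
                                      decoy_rate=0.0, seed=seed)
            for a in ta.assign_all(hits, method="optimized"):
                assert a.rank == "species"
                assert a.taxon == f"Salicornia {truth.assignment[a.query_id]}"

    def test_close_decoys_from_synonym_complex_give_group_calls(self):
        from halobarcode import simulate_hit_table, simulate_species_sequences

        names = {
            f"species{i + 1}": sp
            for i, sp in enumerate(sorted(GROUPS))
        }
        recs, truth = simulate_species_sequences(k=4, n_per=4, seed=0)
        hits = simulate_hit_table(
            truth, score_noise_sd=0.0, decoy_rate=0.999, seed=0,
            species_names=names,
        )
        assignments = ta.assign_all(hits, "optimized", synonym_groups=GROUPS)
        ranks = {a.rank for a in assignments}
        assert ranks <= {"species", "species_group"}
        assert "species_group" in ranks
        for a in assignments:
            if a.rank == "species_group":
                assert a.taxon == "S. europaea complex"
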