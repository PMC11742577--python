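"""Threshold filtering, best-hit selection, OG propagation, concordance."""

import io
import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ogn import zen
from ogn.zen import (
    OgPair,
    ZenThresholds,
    best_hit_per_query,
    concordance,
    coverage_report,
    filter_hits,
    map_to_parent_og,
    propagate_ids,
)
from ogn.refdata import UniProtRecord

from conftest import make_hit


class TestFilterHits:
    @pytest.mark.parametrize(
        "pident,evalue,qcov,tcov,kept",
        [
            (50.0, 1e-7, 0.80, 0.76, True),   # boundary identity passes
            (90.0, 1e-6, 0.90, 0.90, False),  # E-value bound is strict
            (80.0, 1e-20, 0.7475, 0.95, False),  # query coverage just under
            (80.0, 1e-20, 0.95, 0.7475, False),  # target coverage just under
            (80.0, 1e-20, 0.75, 0.75, True),  # boundary coverage passes
            (49.99, 1e-20, 0.95, 0.95, False),
        ],
    )
    def test_threshold_boundaries(self, pident, evalue, qcov, tcov, kept):
        hit = make_hit(pident=pident, evalue=evalue, qcov=qcov, tcov=tcov)
        assert (filter_hits([hit]) == [hit]) is kept

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_order_preserved(self):
        hits = [make_hit(query_id=f"q{i}") for i in range(5)]
        assert filter_hits(hits) == hits

    def test_boundary_grid_matches_predicate(self):
        """10,000-hit grid straddling every threshold boundary equals the
        brute-force predicate applied hit by hit."""
        rng = random.Random(42)
        pidents = [49.99, 50.0, 50.01, 30.0, 99.9]
        evalues = [1e-6, 9.999e-7, 1e-5, 1e-30]
        covs = [0.7499, 0.75, 0.7501, 0.4, 1.0]
        grid = []
        for pident, evalue, qcov, tcov in itertools.product(
            pidents, evalues, covs, covs
        ):
            grid.append(make_hit(pident=pident, evalue=evalue, qcov=qcov,
                                 tcov=tcov, qlen=10000, slen=10000))
        while len(grid) < 10000:
            grid.append(
                make_hit(
                    pident=rng.uniform(0, 100),
                    evalue=10 ** rng.uniform(-40, 0),
                    qcov=rng.uniform(0.01, 1.0),
                    tcov=rng.uniform(0.01, 1.0),
                    qlen=10000,
                    slen=10000,
                )
            )
        kept = set(map(id, filter_hits(grid)))
        for hit in grid:
            expected = (
                hit.pident >= 50.0
                and hit.evalue < 1e-6
                and (hit.qend - hit.qstart + 1) / hit.qlen >= 0.75
                and (hit.send - hit.sstart + 1) / hit.slen >= 0.75
            )
            assert (id(hit) in kept) == expected

    def test_aligned_column_coverage_mode(self):
        hit = zen.AlignmentHit(
            "q", "t", 90.0, aln_length=200, qstart=1, qend=390, sstart=1,
            send=390, qlen=400, slen=400, evalue=1e-20, bitscore=100.0,
        )
        assert filter_hits([hit]) == [hit]  # span 390/400 passes
        t = ZenThresholds(coverage_mode="aligned")
        assert filter_hits([hit], t) == []  # 200/400 aligned columns fails


class TestBestHit:
    def test_highest_bitscore_wins(self):
        a, b = make_hit(bitscore=200), make_hit(bitscore=180, target_id="t2")
        assert best_hit_per_query([b, a]) == {"q1": a}

    def test_evalue_breaks_bitscore_tie(self):
        a = make_hit(bitscore=100, evalue=1e-50)
        b = make_hit(bitscore=100, evalue=1e-40, target_id="t2")
        assert best_hit_per_query([b, a]) == {"q1": a}

    def test_target_id_breaks_full_tie(self):
        a = make_hit(target_id="Bx")
        b = make_hit(target_id="Ax")
        assert best_hit_per_query([a, b])["q1"].target_id == "Ax"

    @settings(max_examples=100, deadline=None)
    @given(st.permutations(list(range(8))), st.data())
    def test_permutation_invariance(self, order, data):
        hits = [
            make_hit(
                query_id=f"q{i % 3}",
                target_id=f"t{i}",
                bitscore=data.draw(st.sampled_from([100.0, 150.0, 200.0])),
                evalue=data.draw(st.sampled_from([1e-10, 1e-20])),
            )
            for i in range(8)
        ]
        baseline = best_hit_per_query(hits)
        shuffled = best_hit_per_query([hits[i] for i in order])
        assert baseline == shuffled


class TestPropagate:
    def test_og_and_description_transferred(self):
        best = {"q1": make_hit(target_id="t1")}
        mapping = propagate_ids(
            best, {"t1": ("75429at38820", "CRAL-TRIO lipid binding domain")}
        )
        assert mapping == {"q1": ("75429at38820", "CRAL-TRIO lipid binding domain")}

    def test_empty_best_map(self):
        assert propagate_ids({}, {}) == {}

    def test_shared_target_shares_og(self):
        best = {
            "q1": make_hit(query_id="q1", target_id="t1"),
            "q2": make_hit(query_id="q2", target_id="t1"),
        }
        mapping = propagate_ids(best, {"t1": ("9at33090", "d")})
        assert mapping["q1"] == mapping["q2"] == ("9at33090", "d")

    def test_missing_target_named_in_error(self):
        with pytest.raises(KeyError, match="t1"):
            propagate_ids({"q1": make_hit(target_id="t1")}, {})

    def test_never_invents_ogs(self):
        rng = random.Random(7)
        target_og = {f"t{i}": (f"{i}at33090", "") for i in range(10)}
        best = {
            f"q{i}": make_hit(query_id=f"q{i}", target_id=f"t{rng.randrange(10)}")
            for i in range(30)
        }
        mapping = propagate_ids(best, target_og)
        assert set(mapping.values()) <= set(target_og.values())


class TestParentOg:
    PAIRS = [
        OgPair("5at4479", "9at38820"),
        OgPair("9at38820", "7at33090"),
        OgPair("7at33090", "3at2759"),
    ]

    def test_single_step(self):
        assert map_to_parent_og("9at38820", self.PAIRS, 33090) == "7at33090"

    def test_chain_resolves_through_levels(self):
        assert map_to_parent_og("5at4479", self.PAIRS, 33090) == "7at33090"
        assert map_to_parent_og("5at4479", self.PAIRS, 2759) == "3at2759"

    def test_og_itself_at_level(self):
        assert map_to_parent_og("7at33090", self.PAIRS, 33090) == "7at33090"

    def test_unreachable_level_gives_none(self):
        assert map_to_parent_og("7at33090", [], 2759) is None

    def test_cycle_is_error(self):
        pairs = [OgPair("1at10", "2at20"), OgPair("2at20", "1at10")]
        with pytest.raises(ValueError, match="cycle"):
            map_to_parent_og("1at10", pairs, 999)

    def test_matches_breadth_first_search_oracle(self):
        """Chain-following equals a BFS over the pair graph on random DAGs."""
        rng = random.Random(11)
        for _ in range(20):
            levels = [4479, 38820, 33090, 2759]
            ogs = {
                lvl: [f"{rng.randrange(100, 999)}at{lvl}" for _ in range(3)]
                for lvl in levels
            }
            pairs = []
            for i in range(len(levels) - 1):
                for og in ogs[levels[i]]:
                    if rng.random() < 0.8:
                        pairs.append(OgPair(og, rng.choice(ogs[levels[i + 1]])))
            parent_of = {p.child_og: p.parent_og for p in pairs}
            for og in ogs[4479] + ogs[38820]:
                for target_level in (33090, 2759):
                    # oracle: explicit breadth-first walk
                    frontier, found = [og], None
                    while frontier:
                        cur = frontier.pop(0)
                        if cur.endswith(f"at{target_level}"):
                            found = cur
                            break
                        if cur in parent_of:
                            frontier.append(parent_of[cur])
                    assert map_to_parent_og(og, pairs, target_level) == found


class TestConcordance:
    PAIRS = [OgPair(f"{i}at4479", f"{i}at33090") for i in range(10)]

    def test_identical_maps_are_fully_concordant(self):
        a = {f"a{i}": (f"{i}at33090", "") for i in range(4)}
        b = {acc: og for acc, (og, _) in a.items()}
        report = concordance(a, b, self.PAIRS, 33090)
        assert (report.n_compared, report.n_exact) == (4, 4)
        assert report.pct_exact == 100.0

    def test_three_of_four(self):
        a = {f"a{i}": (f"{i}at33090", "") for i in range(4)}
        b = {acc: og for acc, (og, _) in a.items()}
        b["a3"] = "99at33090"
        assert concordance(a, b, self.PAIRS, 33090).pct_exact == 75.0

    def test_agreement_via_parent_expansion(self):
        a = {"x": ("3at4479", "")}
        b = {"x": "3at33090"}
        report = concordance(a, b, self.PAIRS, 33090)
        assert report.pct_exact == 100.0

    def test_unresolvable_accessions_excluded(self):
        a = {"x": ("3at33090", ""), "y": ("555at12345", "")}
        b = {"x": "3at33090", "y": "555at12345"}
        report = concordance(a, b, self.PAIRS, 33090)
        assert report.n_compared == 1

    def test_nothing_comparable_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance({"x": ("1at10", "")}, {"y": "1at10"}, [], 33090)


class TestCoverageReport:
    @staticmethod
    def _records(n, n_ukb, source="trembl"):
        return [
            UniProtRecord(
                accession=f"{source}{i}",
                source=source,
                ukb_orthodb=["1at33090"] if i < n_ukb else [],
                sequence="M",
            )
            for i in range(n)
        ]

    def test_zen_expands_coverage(self):
        records = self._records(10, 2)
        mapping = {f"trembl{i}": ("2at33090", "") for i in range(6)}
        report = coverage_report(records, mapping)
        total = report.by_source("total")
        assert total.pct_ukb == 20.0
        assert total.pct_after_zen == 60.0

    def test_empty_zen_changes_nothing(self):
        records = self._records(8, 3)
        report = coverage_report(records, {})
        total = report.by_source("total")
        assert total.n_with_og_after_zen == total.n_with_ukb_og == 3

    def test_full_zen_reaches_100(self):
        records = self._records(5, 0)
        mapping = {r.accession: ("1at33090", "") for r in records}
        assert coverage_report(records, mapping).by_source("total").pct_after_zen == 100.0

    def test_split_by_source(self):
        records = self._records(4, 4, "sprot") + self._records(6, 0, "trembl")
        report = coverage_report(records, {})
        assert report.by_source("sprot").pct_ukb == 100.0
        assert report.by_source("trembl").pct_ukb == 0.0
        assert report.by_source("total").pct_ukb == 40.0

    def test_zero_records_is_error(self):
        with pytest.raises(ValueError):
            coverage_report([], {})


class TestTabularIO:
    def test_hits_round_trip(self):
        hit = make_hit()
        line = "\t".join(
            map(
                str,
                [
                    hit.query_id, hit.target_id, hit.pident, hit.aln_length, 0, 0,
                    hit.qstart, hit.qend, hit.sstart, hit.send, hit.evalue,
                    hit.bitscore, hit.qlen, hit.slen,
                ],
            )
        )
        assert zen.read_hits_tsv(io.StringIO(line + "\n")) == [hit]

    def test_zen_tsv_round_trip(self, tmp_path):
        mapping = {"q2": ("2at33090", "beta"), "q1": ("1at33090", "alpha")}
        path = tmp_path / "zen.tsv"
        zen.write_zen_tsv(mapping, str(path))
        assert zen.read_zen_tsv(str(path)) == mapping
        assert path.read_text().splitlines()[0].startswith("q1\t")  # sorted
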