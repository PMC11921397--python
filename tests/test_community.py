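"""Active-community aggregation, diversity and overlap partitions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qsippy as q
from qsippy.gradient import DataError


def _fixture(missing_medium_core=None):
    """Two 13C cores (+ one 12C) in one group; genus X = {a1, a2}."""
    taxonomy = pd.DataFrame(
        {"phylum": ["P1", "P1", "P2"], "genus": ["X", "X", "Y"]},
        index=["a1", "a2", "a3"],
    )
    cols, meta = {}, []
    abund = {"a1": {"heavy": 10.0, "medium": 5.0, "light": 100.0},
             "a2": {"heavy": 2.0, "medium": 3.0, "light": 7.0},
             "a3": {"heavy": 1.0, "medium": 0.0, "light": 4.0}}
    for core, iso in [("k1", "13C"), ("k2", "13C"), ("k3", "12C")]:
        scale = 2.0 if core == "k2" else 1.0
        for grp, rho in [("light", 1.67), ("medium", 1.72), ("heavy", 1.775)]:
            if core == missing_medium_core and grp == "medium":
                continue
            sid = f"{core}-{grp}"
            cols[sid] = [abund[t][grp] * scale for t in ["a1", "a2", "a3"]]
            meta.append({"sample_id": sid, "core_id": core, "isotope": iso,
                         "wetland": "natural", "redox": "anoxic",
                         "density": rho, "density_group": grp})
    table = q.FeatureTable(pd.DataFrame(cols, index=["a1", "a2", "a3"]),
                           "copies_per_ng_dna", taxonomy)
    metadata = pd.DataFrame(meta).set_index("sample_id", drop=False)
    return table, metadata


ACTIVE = {"natural_anoxic": {"a1", "a2", "a3"}}


class TestTotalActiveAbundance:
    def test_light_excluded_and_genus_summed(self):
        table, md = _fixture()
        prof = q.total_active_abundance(table, md, ACTIVE)
        per_core = prof.per_core
        # genus X in core k1: a1 (10+5) + a2 (2+3) = 20; light never counted
        assert per_core[("natural_anoxic", "k1")]["X"] == pytest.approx(20.0)
        assert per_core[("natural_anoxic", "k2")]["X"] == pytest.approx(40.0)
        row = prof.frame.set_index(["group", "taxon"]).loc[("natural_anoxic", "X")]
        assert row["mean"] == pytest.approx(30.0)
        assert row["n_cores"] == 2
        assert row["sd"] == pytest.approx(np.std([20, 40], ddof=1))
        assert row["se"] == pytest.approx(row["sd"] / np.sqrt(2))

    def test_only_labeled_cores_used(self):
        table, md = _fixture()
        prof = q.total_active_abundance(table, md, ACTIVE)
        assert ("natural_anoxic", "k3") not in prof.per_core.columns

    def test_missing_medium_contributes_zero(self):
        table, md = _fixture(missing_medium_core="k1")
        prof = q.total_active_abundance(table, md, ACTIVE)
        # k1 genus X: heavy only = 10 + 2
        assert prof.per_core[("natural_anoxic", "k1")]["X"] == pytest.approx(12.0)

    def test_conservation_genus_equals_member_sum(self):
        table, md = _fixture()
        prof = q.total_active_abundance(table, md, ACTIVE)
        total_genus = prof.per_core.sum().sum()
        wanted = [s for s in table.sample_ids
                  if md.loc[s, "density_group"] in ("heavy", "medium")
                  and md.loc[s, "isotope"] == "13C"]
        assert total_genus == pytest.approx(table.data[wanted].sum().sum())

    def test_single_core_dispersion_missing(self):
        table, md = _fixture()
        keep = [s for s in table.sample_ids if not s.startswith("k2")]
        prof = q.total_active_abundance(table.select_samples(keep),
                                        md.loc[keep], ACTIVE)
        assert np.isnan(prof.frame["sd"]).all()


class TestBackgroundAbundance:
    def test_all_groups_and_both_isotopes(self):
        table, md = _fixture()
        prof = q.background_abundance(table, md, ACTIVE)
        # k1, genus X: (10+5+100) + (2+3+7) = 127
        assert prof.per_core[("natural_anoxic", "k1")]["X"] == pytest.approx(127.0)
        assert ("natural_anoxic", "k3") in prof.per_core.columns


class TestShannon:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([5], 0.0),
            ([0.5, 0.5], np.log(2)),
        ],
    )
    def test_closed_forms(self, vec, expected):
        assert q.shannon_diversity(vec) == pytest.approx(expected)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            q.shannon_diversity([0.0, 0.0])

    def test_matches_skbio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(4)
        vec = rng.integers(1, 50, size=12)
        assert q.shannon_diversity(vec) == pytest.approx(
            float(skbio_alpha.shannon(vec, base=np.e)))

    @given(st.integers(2, 40))
    def test_uniform_maximizes(self, s):
        assert q.shannon_diversity([1.0] * s) == pytest.approx(np.log(s))
        rng = np.random.default_rng(s)
        skewed = rng.uniform(0.1, 5.0, size=s)
        assert q.shannon_diversity(skewed) <= np.log(s) + 1e-12


class TestOverlap:
    def test_two_sets(self):
        part = q.overlap_partition({"g1": {"A", "B", "C"}, "g2": {"B", "C", "D"}})
        assert part.counts == {"g1": 1, "g2": 1, "g1&g2": 2}
        assert part.regions["g1&g2"] == ["B", "C"]

    def test_identical_sets(self):
        part = q.overlap_partition({"x": {"A", "B"}, "y": {"A", "B"}})
        assert part.counts == {"x": 0, "y": 0, "x&y": 2}

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            q.overlap_partition([("g", {"A"}), ("g", {"B"})])

    @given(st.integers(0, 200))
    def test_disjoint_and_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"s{i}" for i in range(5)]
        sets = {n: set(rng.choice(60, size=20, replace=False).tolist())
                for n in names}
        part = q.overlap_partition(sets)
        union = set().union(*sets.values())
        assert part.total() == len(union)
        seen = [m for members in part.regions.values() for m in members]
        assert len(seen) == len(set(seen))  # pairwise disjoint
        # regions reconstruct the original sets exactly
        for n in names:
            rebuilt = {m for sig, members in part.regions.items()
                       if n in sig.split("&") for m in members}
            assert rebuilt == {str(x) for x in sets[n]}
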