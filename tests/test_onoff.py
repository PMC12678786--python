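"""Binarization, offonome definition, Venn partitions, and count filtering."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from offonome import (
    CountFilterRule,
    LSSMatrix,
    OnOffMatrix,
    OnOffParams,
    call_on_off,
    count_filter,
    define_offonome,
    overlap_fraction,
    venn_partition,
)


def lss_of(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return LSSMatrix(
        tuple(f"g{i}" for i in range(values.shape[0])),
        tuple(f"s{j}" for j in range(values.shape[1])),
        values,
    )


def states_of(state):
    state = np.atleast_2d(np.asarray(state))
    return OnOffMatrix(
        tuple(f"g{i}" for i in range(state.shape[0])),
        tuple(f"s{j}" for j in range(state.shape[1])),
        state,
    )


# ---------------------------------------------------------------------------
# on/off calls


def test_threshold_is_strictly_greater():
    states = call_on_off(lss_of([[0.61, 0.60, 0.59, 0.0]]), OnOffParams(0.6))
    assert states.state.tolist() == [[1, 0, 0, 0]]


def test_all_zero_row_is_all_off():
    states = call_on_off(lss_of([[0.0] * 5]))
    assert not states.state.any()


def test_out_of_range_lss_rejected():
    bad = LSSMatrix.__new__(LSSMatrix)  # bypass constructor validation
    bad.gene_ids, bad.sample_ids = ("g",), ("s",)
    bad.values = np.array([[1.4]])
    with pytest.raises(ValueError):
        call_on_off(bad)


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 9999), t1=st.floats(0.1, 0.9), t2=st.floats(0.1, 0.9))
def test_raising_threshold_never_turns_off_to_on(seed, t1, t2):
    rng = np.random.default_rng(seed)
    lss = lss_of(rng.random((4, 6)))
    lo, hi = sorted((t1, t2))
    on_lo = call_on_off(lss, OnOffParams(lo)).state
    on_hi = call_on_off(lss, OnOffParams(hi)).state
    assert (on_hi <= on_lo).all()


# ---------------------------------------------------------------------------
# offonome definition


@pytest.mark.parametrize("n_off,included", [(2, True), (1, False), (10, True)])
def test_membership_boundary_inclusive(n_off, included):
    row = [0] * n_off + [1] * (10 - n_off)
    offo = define_offonome(states_of([row]), min_off_frac=0.20)
    assert ("g0" in offo.gene_ids) is included
    assert offo.off_fraction["g0"] == pytest.approx(n_off / 10)


def test_degenerate_matrices():
    assert define_offonome(states_of(np.ones((4, 6), dtype=int))).gene_ids == frozenset()
    all_off = define_offonome(states_of(np.zeros((4, 6), dtype=int)))
    assert all_off.gene_ids == frozenset({"g0", "g1", "g2", "g3"})


def test_lowering_min_off_frac_never_removes_genes():
    rng = np.random.default_rng(3)
    states = states_of(rng.integers(0, 2, size=(20, 10)))
    big = define_offonome(states, 0.5).gene_ids
    small = define_offonome(states, 0.2).gene_ids
    assert big <= small


# ---------------------------------------------------------------------------
# Venn partitions


def sets_with_partition(regions):
    """Construct concrete gene sets realizing the given exclusive counts."""
    counter = itertools.count()
    names = sorted({n for key in regions for n in key.split("&")})
    sets = {n: set() for n in names}
    for key, count in regions.items():
        for _ in range(count):
            g = next(counter)
            for n in key.split("&"):
                sets[n].add(g)
    return sets


def test_two_cohort_union_from_component_counts():
    """|A|=5434, |B|=5292 with 4984 shared -> union 5742, 450/308 specific."""
    sets = sets_with_partition({"LUAD&LUSC": 4984, "LUAD": 450, "LUSC": 308})
    assert len(sets["LUAD"]) == 5434
    assert len(sets["LUSC"]) == 5292
    result = venn_partition(sets)
    assert result.union_size == 5742
    assert result.regions == {"LUAD&LUSC": 4984, "LUAD": 450, "LUSC": 308}


def test_three_cohort_partition_sums_to_union():
    regions = {
        "HNSC&LUAD&LUSC": 4813,
        "HNSC&LUSC": 288,
        "LUAD&LUSC": 171,
        "HNSC&LUAD": 164,
        "HNSC": 586,
        "LUAD": 286,
        "LUSC": 20,
    }
    result = venn_partition(sets_with_partition(regions))
    assert result.union_size == 6328
    assert result.regions == regions
    assert sum(result.regions.values()) == result.union_size


def test_disjoint_pair():
    result = venn_partition({"A": {"g1"}, "B": {"g2"}})
    assert result.regions == {"A&B": 0, "A": 1, "B": 1}
    assert result.union_size == 2


def test_partition_requires_two_or_three_sets():
    with pytest.raises(ValueError):
        venn_partition({"A": {"g"}})


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 9999))
def test_partition_permutation_invariant_and_inclusion_exclusion(seed):
    rng = np.random.default_rng(seed)
    universe = list(range(60))
    sets = {n: set(rng.choice(universe, size=rng.integers(5, 40), replace=False).tolist())
            for n in ("X", "Y", "Z")}
    result = venn_partition(sets)
    assert sum(result.regions.values()) == result.union_size == len(set().union(*sets.values()))
    renamed = venn_partition({"Z": sets["Z"], "X": sets["X"], "Y": sets["Y"]})
    assert renamed.regions == result.regions


# ---------------------------------------------------------------------------
# count filter


def test_count_filter_trivial_cases():
    counts = pd.DataFrame(
        {
            "s1": [0, 50, 50, 50],
            "s2": [0, 50, 50, 50],
            "s3": [0, 50, 50, 50],
            "s4": [0, 50, 4, 50],
        },
        index=["zero", "high", "mixed", "high2"],
    )
    kept = count_filter(counts)
    assert "zero" not in kept
    assert {"high", "high2"} <= kept


def test_count_filter_matches_hand_executed_rule():
    """6-gene, 5-sample fixture evaluated by hand against the documented rule."""
    counts = pd.DataFrame(
        [
            [100, 100, 100, 100, 100],  # clearly kept
            [0, 0, 0, 0, 0],            # zero -> dropped
            [3, 3, 3, 3, 2],            # total 14 < 15 -> dropped
            [4, 4, 4, 4, 4],            # CPM ~8889 >= cutoff in all 5, total 20 -> kept
            [20, 0, 0, 0, 0],           # CPM >= cutoff in only 1 of 5 -> dropped
            [973, 993, 993, 993, 994],  # library filler, kept
        ],
        index=list("abcdef"),
        columns=[f"s{j}" for j in range(5)],
    )
    # hand evaluation: every library totals 1100, so the CPM cutoff is
    # 10/1100*1e6 = 9090.9 and a gene must reach it in all 5 samples with
    # total count >= 15.  a: 90909 CPM everywhere -> kept.  b: zero.  c: 2727
    # CPM, total 14 -> dropped twice over.  d: 3636 CPM < cutoff -> dropped.
    # e: 18182 CPM in one sample only -> dropped.  f: ~900k CPM -> kept.
    assert counts.sum(axis=0).tolist() == [1100] * 5
    assert count_filter(counts) == {"a", "f"}


def test_count_filter_group_sizes_shrink_toward_large_n():
    # 24 samples in one group: min sample size = 10 + (24-10)*0.7 = 19.8
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(50, 100, size=(3, 24)))
    counts.iloc[1, :5] = 0  # still >= cutoff in 19 samples < 19.8 -> dropped
    counts.index = ["keep", "borderline", "keep2"]
    kept = count_filter(counts)
    assert kept == {"keep", "keep2"}


def test_count_filter_rejects_zero_library():
    counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]}, index=["a", "b"])
    with pytest.raises(ValueError):
        count_filter(counts)


def test_count_filter_agrees_with_edger(tmp_path):
    """Cross-check against edgeR::filterByExpr on a random fixture."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(20, 6)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
    counts.iloc[:8] = rng.integers(0, 8, size=(8, 6))
    counts.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = tmp_path / "filt.R"
    script.write_text(
        'suppressMessages(library(edgeR))\n'
        'm <- as.matrix(read.table("counts.tsv", header=TRUE, row.names=1, sep="\\t"))\n'
        'keep <- suppressMessages(filterByExpr(m))\n'
        'writeLines(rownames(m)[keep], "keep.txt")\n'
    )
    subprocess.run(["Rscript", str(script)], cwd=tmp_path, check=True,
                   capture_output=True, timeout=120)
    expected = frozenset((tmp_path / "keep.txt").read_text().split())
    assert count_filter(counts) == expected


# ---------------------------------------------------------------------------
# overlap fraction


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({1, 2}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        (set(range(50)), set(range(17, 100)), 33 / 50),
    ],
)
def test_overlap_fraction(a, b, expected):
    assert overlap_fraction(a, b) == pytest.approx(expected)


def test_overlap_fraction_rejects_empty_first_set():
    with pytest.raises(ValueError):
        overlap_fraction(set(), {1})
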