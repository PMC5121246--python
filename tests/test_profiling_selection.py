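"""Length profiles, catalog homology matching and four-criterion selection."""

import random

import pytest

from srnatransfer.io_formats import CollapsedLibrary, ReferenceSet
from srnatransfer.profiling_selection import (
    SelectionParams,
    annotate_candidates,
    best_homolog,
    catalog_match,
    length_profile,
    profile_modes,
    select_candidates,
)
from srnatransfer.set_pipeline import PipelineResult, run_pipeline


def _random_seq(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


def levenshtein(a, b):
    """Textbook dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------- profiles


def test_profile_trivial_cases():
    lib = CollapsedLibrary(role="LC", counts={"A" * 24: 7})
    profile = length_profile(lib)
    assert profile[24] == 1.0
    assert sum(profile.values()) == pytest.approx(1.0)

    lib2 = CollapsedLibrary(role="WN", counts={"A" * 22: 1, "G" * 29: 1})
    profile2 = length_profile(lib2)
    assert profile2[22] == 0.5 and profile2[29] == 0.5

    with pytest.raises(ValueError):
        length_profile(CollapsedLibrary(role="WN", counts={}))


def test_profile_is_read_weighted_mixture():
    a = CollapsedLibrary(role="x", counts={"A" * 20: 3})
    b = CollapsedLibrary(role="x", counts={"G" * 30: 1})
    merged = CollapsedLibrary(role="x", counts={"A" * 20: 3, "G" * 30: 1})
    pa, pb, pm = length_profile(a), length_profile(b), length_profile(merged)
    for length in pm:
        expected = (pa[length] * 3 + pb[length] * 1) / 4
        assert pm[length] == pytest.approx(expected)


def test_simulated_profiles_show_insect_and_plant_peaks(filtered_libraries):
    """WN: miRNA peak at 22 and piRNA peak in 29-30; leaves: 24-nt mode."""
    wn = length_profile(filtered_libraries["WN"])
    assert profile_modes(wn)[0] == 22
    long_mode = max(range(26, 41), key=lambda L: wn[L])
    assert long_mode in (29, 30)
    for role in ("LC", "LW", "LE"):
        assert profile_modes(length_profile(filtered_libraries[role]))[0] == 24


# ---------------------------------------------------------------- catalog


def test_catalog_exact_match_and_boundary():
    seq = "UAGUAGCUAACGACGAUUCCUUU"
    catalog = ReferenceSet("cat", "mirna_catalog", [("wfl-cand-3182", seq)])
    lib = CollapsedLibrary(role="WN", counts={seq: 5})
    assert catalog_match(lib, catalog, mode="exact") == {seq: ("wfl-cand-3182", 0)}

    variant = "CAGUAGCUAACGACGAUUCCUUU"  # one substitution
    lib2 = CollapsedLibrary(role="WN", counts={variant: 1})
    assert catalog_match(lib2, catalog, mode="exact") == {}
    assert catalog_match(lib2, catalog, mode="edit", k=0) == {}
    assert catalog_match(lib2, catalog, mode="edit", k=1) == {variant: ("wfl-cand-3182", 1)}


def test_catalog_edit_mode_matches_dp_oracle():
    rng = random.Random(23)
    catalog_entries = [(f"m{i}", _random_seq(rng, rng.randint(20, 24))) for i in range(30)]
    catalog = ReferenceSet("cat", "mirna_catalog", catalog_entries)
    queries = {}
    for _ in range(60):
        if rng.random() < 0.5:
            base = list(catalog_entries[rng.randrange(30)][1])
            for _ in range(rng.randint(0, 3)):
                base[rng.randrange(len(base))] = rng.choice("ACGU")
            queries["".join(base)] = 1
        else:
            queries[_random_seq(rng, rng.randint(18, 30))] = 1
    lib = CollapsedLibrary(role="WN", counts=queries)
    k = 2
    got = catalog_match(lib, catalog, mode="edit", k=k)
    for seq in queries:
        dists = [levenshtein(seq, cseq) for _, cseq in catalog_entries]
        best = min(dists)
        if best <= k:
            expect_id = catalog_entries[dists.index(best)][0]
            assert got[seq] == (expect_id, best)
        else:
            assert seq not in got


def test_empty_catalog_raises():
    lib = CollapsedLibrary(role="WN", counts={"A" * 20: 1})
    with pytest.raises(ValueError):
        catalog_match(lib, ReferenceSet("cat", "mirna_catalog", []))


# ---------------------------------------------------------------- selection


def _toy_libraries(counts_by_seq):
    roles = ("PC", "PW", "LC", "LW", "LE", "WN")
    libs = {}
    for i, role in enumerate(roles):
        counts = {s: c[i] for s, c in counts_by_seq.items() if c[i] > 0}
        libs[role] = CollapsedLibrary(role=role, counts=counts)
    return libs


def test_constructed_candidate_passes_all_criteria():
    seq = "U" * 23
    libs = _toy_libraries({seq: (0, 3, 0, 2, 0, 100)})
    result = PipelineResult(phloem_set={seq}, leaf_set={seq}, final_set={seq})
    catalog = ReferenceSet("cat", "mirna_catalog", [("x|insect", "A" * 23)])
    cands = annotate_candidates(result, libs, catalog, SelectionParams(top_k_wn=10))
    assert len(cands) == 1
    c = cands[0]
    assert c.length_ok and c.abundant_in_wn and c.presence_pattern_ok and c.homology_pref_ok
    assert c.selected
    assert select_candidates(result, libs, catalog, SelectionParams(top_k_wn=10)) == cands


def test_21nt_candidate_fails_length_criterion():
    seq = "U" * 21
    libs = _toy_libraries({seq: (0, 3, 0, 2, 0, 100)})
    result = PipelineResult(phloem_set={seq}, leaf_set={seq}, final_set={seq})
    catalog = ReferenceSet("cat", "mirna_catalog", [("x|insect", "A" * 23)])
    cands = annotate_candidates(result, libs, catalog)
    assert not cands[0].length_ok
    assert select_candidates(result, libs, catalog) == []


def test_selection_equals_brute_force_predicates():
    """100 randomized candidates: selection == conjunction of the 4 criteria."""
    rng = random.Random(31)
    counts_by_seq = {}
    for _ in range(100):
        seq = _random_seq(rng, rng.randint(19, 26))
        counts_by_seq[seq] = (
            rng.choice([0, 0, 2]),
            rng.choice([0, 1, 5]),
            rng.choice([0, 0, 1]),
            rng.choice([0, 2, 8]),
            rng.choice([0, 0, 3]),
            rng.choice([0, 10, 200, 1000]),
        )
    libs = _toy_libraries(counts_by_seq)
    final = set(counts_by_seq)
    result = PipelineResult(phloem_set=final, leaf_set=final, final_set=final)
    catalog = ReferenceSet(
        "cat",
        "mirna_catalog",
        [("ins|insect", _random_seq(rng, 22)), ("vert|vertebrate", _random_seq(rng, 22))],
    )
    params = SelectionParams(top_k_wn=20)
    cands = annotate_candidates(result, libs, catalog, params)

    wn = libs["WN"]
    ordered = sorted(final, key=lambda s: (-wn.counts.get(s, 0), s))
    for c in cands:
        assert c.length_ok == (params.min_len <= len(c.seq) <= params.max_len)
        assert c.abundant_in_wn == (ordered.index(c.seq) + 1 <= params.top_k_wn)
        expected_presence = all(
            libs[r].counts.get(c.seq, 0) > 0 for r in ("LW", "PW", "WN")
        ) and all(libs[r].counts.get(c.seq, 0) == 0 for r in ("LC", "LE", "PC"))
        assert c.presence_pattern_ok == expected_presence
        homolog = best_homolog(c.seq, catalog, params.homology_k)
        if homolog is None:
            assert c.homology_pref_ok
        else:
            assert c.homology_pref_ok == homolog[0].endswith("|insect")
        assert c.selected == (
            c.length_ok and c.abundant_in_wn and c.presence_pattern_ok and c.homology_pref_ok
        )
    selected = select_candidates(result, libs, catalog, params)
    assert [c.seq for c in selected] == [c.seq for c in cands if c.selected]


def test_selection_monotone_in_top_k(sim_experiment, filtered_libraries):
    _, references, _, _ = sim_experiment
    result = run_pipeline(filtered_libraries, references["genome"])
    catalog = references["mirna_catalog"]
    previous: set[str] = set()
    for top_k in (5, 15, 50):
        now = {
            c.seq
            for c in select_candidates(
                result, filtered_libraries, catalog, SelectionParams(top_k_wn=top_k)
            )
        }
        assert previous <= now
        previous = now


def test_selected_candidates_subset_of_final(sim_experiment, filtered_libraries):
    _, references, _, truth = sim_experiment
    result = run_pipeline(filtered_libraries, references["genome"])
    cands = select_candidates(result, filtered_libraries, references["mirna_catalog"])
    assert {c.seq for c in cands} <= result.final_set
    for c in cands:
        assert c.presence_pattern_ok and c.selected
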