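import numpy as np
import pandas as pd
import pytest

from helpers import conditions_df, contacts_df, persons_df
from hhseg.household_builder import build_households
from hhseg.profiling import (
    age_band,
    age_sex_density,
    criteria_table,
    mh_breakdowns,
    prevalence_table,
    round_half_up,
    service_intersections,
    size_summary,
    table_percent,
)
from hhseg.segmentation import run_segmentation
from hhseg.synthetic_data import (
    SyntheticConfig,
    generate_population,
    generate_unmet_need_strata,
)


def test_round_half_up():
    assert round_half_up(2.5) == 3
    assert round_half_up(3.5) == 4  # not banker's rounding
    assert round_half_up(2.45, 1) == 2.5
    assert round_half_up(-0.0) == 0


def test_table_percent_styles():
    assert table_percent(21, 21527) == 0.1       # tiny cells: 1 dp
    assert table_percent(92, 266939) == 0.03     # below 0.05%: 2 dp
    assert table_percent(4528, 266939) == 1.7    # below 2%: 1 dp
    assert table_percent(717, 21527) == 3        # integers otherwise
    assert table_percent(11714, 245412) == 5
    assert table_percent(19801, 21527) == 92
    assert table_percent(0, 0) == 0.0


def test_criteria_table_complex_column_100(strong_workspace):
    table = criteria_table(strong_workspace["segments"]).set_index("criterion")
    for row in ("criterion_1_adult_physical_and_mental",
                "criterion_2_child_problem",
                "criterion_3_any_vulnerability",
                "criterion_4_top_spend"):
        assert table.loc[row, "complex_pct"] == 100


def test_criteria_table_partition(strong_workspace):
    table = criteria_table(strong_workspace["segments"])
    assert (table["other_count"] + table["complex_count"]
            == table["total_count"]).all()
    assert table.attrs["n_other"] + table.attrs["n_complex"] \
        == table.attrs["n_total"]


def test_criteria_table_hand_tally(cfg):
    """10-household toy with hand-evaluated flags."""
    flags = pd.DataFrame({
        "household_id": [f"h{i}" for i in range(10)],
        "c1_adult_phys_and_mental": [1, 1, 1, 0, 0, 1, 0, 0, 1, 0],
        "c2_child_problem":          [1, 1, 1, 1, 0, 0, 0, 0, 1, 0],
        "homelessness": [0] * 10,
        "high_ae":       [0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
        "substance_abuse": [0] * 10,
        "lone_parent":   [1, 0, 1, 0, 0, 0, 1, 0, 1, 0],
        "child_in_care": [0] * 10,
        "deprived":      [0, 1, 0, 1, 0, 0, 0, 0, 1, 0],
        "multi_service": [1, 0, 0, 0, 0, 1, 0, 0, 1, 0],
        "c4_top_spend":  [1, 1, 0, 0, 1, 0, 0, 0, 1, 0],
        "per_capita_cost": np.arange(10, dtype=float),
    }).astype({c: bool for c in (
        "c1_adult_phys_and_mental", "c2_child_problem", "homelessness",
        "high_ae", "substance_abuse", "lone_parent", "child_in_care",
        "deprived", "multi_service", "c4_top_spend")})
    flags["c3_vulnerability"] = flags[[
        "homelessness", "high_ae", "substance_abuse", "lone_parent",
        "child_in_care", "deprived", "multi_service"]].any(axis=1)
    flags["in_segment"] = (flags["c1_adult_phys_and_mental"]
                           & flags["c2_child_problem"]
                           & flags["c3_vulnerability"]
                           & flags["c4_top_spend"])
    # hand check: households h0, h1, h8 are in the segment
    assert list(flags.loc[flags["in_segment"], "household_id"]) \
        == ["h0", "h1", "h8"]
    table = criteria_table(flags).set_index("criterion")
    assert table.attrs["n_complex"] == 3
    assert table.loc["criterion_1_adult_physical_and_mental","total_count"] == 5
    assert table.loc["criterion_1_adult_physical_and_mental","complex_count"] == 3
    assert table.loc["criterion_1_adult_physical_and_mental","other_count"] == 2
    assert table.loc["criterion_1_adult_physical_and_mental","total_pct"] == 50
    assert table.loc["c3_lone_parent", "total_count"] == 4
    assert table.loc["c3_lone_parent", "complex_pct"] == 67
    assert table.loc["c3_high_ae", "other_pct"] == 0.0
    assert table.loc["criterion_4_top_spend", "complex_pct"] == 100


def _toy_workspace(cfg):
    persons = persons_df([
        {"person_id": "a1", "household_id": "h1", "age": 40, "sex": "F"},
        {"person_id": "c1", "household_id": "h1", "age": 14, "sex": "F"},
        {"person_id": "a2", "household_id": "h2", "age": 30, "sex": "M"},
        {"person_id": "c2", "household_id": "h2", "age": 2, "sex": "M"},
        {"person_id": "a3", "household_id": "h3", "age": 50, "sex": "F"},
        {"person_id": "c3", "household_id": "h3", "age": 10, "sex": "M"},
        {"person_id": "a4", "household_id": "h4", "age": 25, "sex": "M"},
        {"person_id": "c4", "household_id": "h4", "age": 5, "sex": "F"},
    ])
    conditions = conditions_df([
        ("a1", "asthma"), ("a1", "depression"), ("c1", "anxiety"),
        ("a2", "diabetes"),
    ])
    contacts = contacts_df([
        {"person_id": "a1", "sector": "primary_care", "n_contacts": 4},
        {"person_id": "a1", "sector": "mental_health",
         "reason_class": "mental_health", "n_contacts": 2},
        {"person_id": "c1", "sector": "community", "n_contacts": 1},
        {"person_id": "c1", "sector": "ae", "reason_class": "self_harm",
         "emergency": True, "n_contacts": 2},
        {"person_id": "a2", "sector": "primary_care", "n_contacts": 1},
        {"person_id": "a3", "sector": "outpatient", "n_contacts": 1},
    ])
    return run_segmentation(persons, conditions, contacts, cfg), conditions, contacts


def test_toy_segment_and_intersections(cfg):
    ws, conditions, contacts = _toy_workspace(cfg)
    seg = ws["segments"].set_index("household_id")
    assert bool(seg.loc["h1", "in_segment"])
    assert not seg.loc[["h2", "h3", "h4"], "in_segment"].any()
    inter = service_intersections(ws["cohort_members"], contacts,
                                  ws["segments"])
    # h1 uses {ae, community, mental_health, primary_care}
    assert inter.attrs["n_complex_households"] == 1
    assert inter["n_households"].sum() == 1
    assert inter.loc[0, "sectors"] == "ae|community|mental_health|primary_care"


def test_intersections_partition_and_bruteforce(cfg):
    rng = np.random.default_rng(3)
    persons, conditions, contacts, truth = generate_population(
        SyntheticConfig(n_households=120, planted_complex_fraction=0.2, seed=3))
    ws = run_segmentation(persons, conditions, contacts, cfg)
    inter = service_intersections(ws["cohort_members"], contacts,
                                  ws["segments"])
    n_complex = int(ws["segments"]["in_segment"].sum())
    assert inter["n_households"].sum() == n_complex
    # brute-force tally
    complex_ids = set(ws["segments"].loc[ws["segments"]["in_segment"],
                                         "household_id"])
    hh_of = dict(zip(ws["cohort_members"]["person_id"],
                     ws["cohort_members"]["household_id"]))
    subsets: dict[str, set] = {h: set() for h in complex_ids}
    for rec in contacts.to_dict("records"):
        h = hh_of.get(rec["person_id"])
        if h in subsets:
            subsets[h].add(rec["sector"])
    expected: dict[str, int] = {}
    for sectors in subsets.values():
        key = "|".join(sorted(sectors))
        expected[key] = expected.get(key, 0) + 1
    got = dict(zip(inter["sectors"], inter["n_households"]))
    assert got == expected


def test_prevalence_nobody_has_condition(cfg, strong_workspace):
    ws = strong_workspace
    conditions = conditions_df([])
    table = prevalence_table(ws["cohort_members"], conditions,
                             ws["segments"], cfg).set_index("condition")
    assert (table.loc["dementia"] == 0).all()


def test_prevalence_partition_counts(cfg, strong_workspace):
    ws = strong_workspace
    table = prevalence_table(
        ws["cohort_members"],
        conditions_df([]),
        ws["segments"], cfg)
    demo = table.attrs["demographics"]
    assert demo["n"].sum() == len(ws["cohort_members"])


def test_prevalence_matches_planted_rate(cfg):
    """Planted adult mental prevalence 0.20 shows up in the complex-adult
    cell at the rate the generative model implies.

    Planted households force one adult mental flag whenever sampling
    yields none (the c1 guarantee), so with k adults the expected number
    flagged is k*p + (1-p)^k; the observed cell must sit within 3 SE of
    that expectation computed from the realised household compositions.
    """
    p = 0.20
    scfg = SyntheticConfig(
        n_households=3000, planted_complex_fraction=0.15, seed=11,
        adult_physical_prev=(0.9, 0.1), adult_mental_prev=(p, 0.05),
        child_problem_prev=(0.9, 0.05),
    )
    persons, conditions, contacts, truth = generate_population(scfg)
    households, members, _ = build_households(persons, cfg)
    segments = truth.rename(columns={"planted": "in_segment"})[
        ["household_id", "in_segment"]]
    table = prevalence_table(members, conditions, segments, cfg)
    ment_codes = sorted(cfg.mental_conditions)
    # each flagged adult carries exactly one mental code, so the cell sum
    # over codes equals the fraction of flagged adults
    got = table.set_index("condition").loc[ment_codes,
                                           "adults_complex_pct"].sum()
    planted_ids = set(truth.loc[truth["planted"], "household_id"])
    adults_per_hh = (
        persons.loc[persons["household_id"].isin(planted_ids)
                    & (persons["age"] >= 17)]
        .groupby("household_id").size()
    )
    k = adults_per_hh.to_numpy()
    expected = 100.0 * (k * p + (1 - p) ** k).sum() / k.sum()
    se = 100 * np.sqrt(p * (1 - p) / k.sum())
    assert got == pytest.approx(expected, abs=3 * se + 0.5)


def test_size_summary_and_age_sex_density(cfg, strong_workspace):
    ws = strong_workspace
    sizes = size_summary(ws["segments"], ws["cohort"]).set_index("group")
    assert set(sizes.index) == {"complex", "other"}
    assert sizes.loc["complex", "mean_size"] > 0
    density = age_sex_density(ws["cohort_members"], ws["segments"], cfg)
    assert density["count"].sum() == len(ws["cohort_members"])


def test_age_band_edges():
    bands = age_band(pd.Series([0, 4, 5, 11, 12, 16, 17, 24, 25, 44, 45,
                                64, 65, 90]))
    assert list(bands) == ["0-4", "0-4", "5-11", "5-11", "12-16", "12-16",
                           "17-24", "17-24", "25-44", "25-44", "45-64",
                           "45-64", "65+", "65+"]


def test_mh_breakdowns_empty(cfg, strong_workspace):
    ws = strong_workspace
    reason, ae_mh = mh_breakdowns(ws["cohort_members"], contacts_df([]),
                                  ws["segments"], cfg)
    assert reason.empty
    assert ae_mh["attendances"].sum() == 0


def test_mh_breakdowns_match_naive_tally(cfg):
    ws, conditions, contacts = _toy_workspace(cfg)
    reason, ae_mh = mh_breakdowns(ws["cohort_members"], contacts,
                                  ws["segments"], cfg)
    reason = reason.set_index(["group", "reason_class"])["contact_count"]
    # h1 is the only complex household; a1 has 2 MH contacts, c1 has 2
    # emergency self-harm attendances
    assert reason[("complex", "mental_health")] == 2
    assert reason[("complex", "self_harm")] == 2
    assert ("other",) not in {i[:1] for i in reason.index} or \
        reason.loc["other"].sum() == 0
    by_cell = ae_mh.set_index(["band", "sex"])["attendances"]
    assert by_cell[("12-16", "F")] == 2
    assert by_cell.sum() == 2


def test_teen_girl_concentration_is_maximum(cfg):
    """Concentrating the emergency-MH rate on girls 12-16 makes that cell
    the maximum of the age/sex breakdown."""
    scfg = SyntheticConfig(
        n_households=2500, planted_complex_fraction=0.15, seed=19,
        teen_girl_mh_odds_mult=25.0,
        emergency_mh_base_prob=(0.05, 0.01),
    )
    persons, conditions, contacts, truth = generate_population(scfg)
    contacts, _ = generate_unmet_need_strata(persons, conditions, contacts,
                                             truth, scfg)
    ws = run_segmentation(persons, conditions, contacts, cfg)
    _, ae_mh = mh_breakdowns(ws["cohort_members"], contacts, ws["segments"],
                             cfg)
    by_cell = ae_mh.set_index(["band", "sex"])["attendances"]
    assert by_cell.idxmax() == ("12-16", "F")


def test_report_generation_pure(cfg, strong_workspace):
    ws = strong_workspace
    t1 = criteria_table(ws["segments"])
    t2 = criteria_table(ws["segments"])
    pd.testing.assert_frame_equal(t1, t2)
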