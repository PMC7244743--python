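"""The named experiment scans: titrations, Pareto curves, decomposition, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from conftest import TOY_EFFICIENCY
from nodulefba import experiments as ex
from nodulefba.cli import main as cli_main
from nodulefba.engine import optimize_growth

E_GRID = np.arange(0.0, 301.0, 10.0)
F_GRID = np.arange(0.0, 0.2501, 0.01)


# ---------------------------------------------------------------------------
# ammonium titration (exogenous-nitrogen trade-off)


@pytest.fixture(scope="module")
def titration_eff(holobiont_session):
    grid = np.arange(0.0, 31.0, 5.0)
    return ex.ammonium_titration(holobiont_session, "vary_efficiency", grid).table


@pytest.fixture(scope="module")
def titration_nod(holobiont_session):
    grid = np.arange(0.0, 31.0, 5.0)
    return ex.ammonium_titration(
        holobiont_session, "vary_nodulation", grid, efficiency=TOY_EFFICIENCY
    ).table


def test_growth_is_monotone_in_ammonium_availability(titration_eff, titration_nod):
    for table in (titration_eff, titration_nod):
        g = table.growth_per_day.to_numpy()
        assert (np.diff(g) >= -1e-6).all()


def test_zero_ammonium_limit_equals_n2_only_optimum(holobiont_session, titration_eff):
    n2_only = optimize_growth(holobiont_session).objective_value * 24.0
    assert titration_eff.growth_per_day.iloc[0] == pytest.approx(n2_only, rel=1e-6)


def test_saturating_ammonium_approaches_non_nodulated_maximum(
    holobiont_session, titration_nod
):
    decomp = ex.cost_decomposition(holobiont_session)
    ammonium_max = decomp.growth["ammonium_non_nodulated"]
    tail = titration_nod.iloc[-1]
    assert tail.growth_per_day == pytest.approx(ammonium_max, rel=0.01)
    assert tail.f_opt < 0.005  # nodulation abandoned when nitrogen is free


def test_optimised_nodulation_never_loses_to_fixed_nodulation(
    titration_eff, titration_nod
):
    # the free-nodulation curve can shed the fixed 2% nodule burden; allow a
    # small tolerance at the N2-only end where the fixed-f build instead
    # enjoys a free nitrogenase flux
    for ge, gn in zip(titration_eff.growth_per_day, titration_nod.growth_per_day):
        assert gn >= ge * 0.98 - 1e-9


# ---------------------------------------------------------------------------
# Pareto: fixation efficiency


@pytest.fixture(scope="module")
def pareto_default(holobiont_session):
    return ex.pareto_fixation(holobiont_session, E_GRID).table


@pytest.fixture(scope="module")
def pareto_uncapped(holobiont_session):
    return ex.pareto_fixation(holobiont_session, E_GRID, zone3_o2_cap="none").table


def test_zero_efficiency_means_zero_growth(pareto_default):
    assert pareto_default.growth_per_day.iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_oxygen_cap_collapses_the_symbiosis_just_past_the_optimum(pareto_default):
    t = pareto_default
    feasible = t[t.status == "optimal"]
    assert len(feasible) < len(t), "expected infeasible points at high efficiency"
    e_opt = t.loc[t.growth_per_day.idxmax(), "efficiency"]
    e_last = feasible.efficiency.max()
    assert e_opt > 0
    assert e_last <= 1.25 * e_opt  # sharp collapse shortly past the optimum


def test_uncapped_oxygen_gives_graded_decline_instead(pareto_uncapped):
    t = pareto_uncapped
    assert (t.status == "optimal").all()
    i = t.growth_per_day.idxmax()
    assert 0 < i < len(t) - 1
    # interior optimum, still feasible (with lower growth) at the grid's end
    assert t.growth_per_day.iloc[-1] > 0
    assert t.growth_per_day.iloc[-1] < t.growth_per_day[i]
    rise = (t.growth_per_day[i] - t.growth_per_day[0]) / t.efficiency[i]
    fall = (t.growth_per_day[i] - t.growth_per_day.iloc[-1]) / (
        t.efficiency.iloc[-1] - t.efficiency[i]
    )
    assert rise > fall  # cost of over-fixing is milder than nitrogen starvation


# ---------------------------------------------------------------------------
# Pareto: nodulation fraction


@pytest.fixture(scope="module")
def pareto_f(holobiont_session):
    return ex.pareto_nodulation(
        holobiont_session, F_GRID, efficiency=TOY_EFFICIENCY
    ).table


def test_zero_nodulation_means_zero_growth_under_n2(pareto_f):
    assert pareto_f.growth_per_day.iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_nodulation_curve_has_single_interior_optimum_and_steeper_rise(pareto_f):
    t = pareto_f
    i = t.growth_per_day.idxmax()
    assert 0 < i < len(t) - 1
    below = (t.growth_per_day[i] - t.growth_per_day[0]) / (t.f[i] - t.f[0])
    above = (t.growth_per_day[i] - t.growth_per_day.iloc[-1]) / (t.f.iloc[-1] - t.f[i])
    assert below > above > 0


def test_nodulation_curve_is_unimodal_with_high_f_collapse(pareto_f):
    # rises to a single optimum, declines beyond it, and collapses to
    # infeasibility once the forced fixation outruns the plant's carbon supply
    t = pareto_f
    g = t.growth_per_day.to_numpy()
    i = int(t.growth_per_day.idxmax())
    assert (np.diff(g[: i + 1]) >= -1e-6).all()
    assert (np.diff(g[i:]) <= 1e-6).all()
    assert (t.status != "optimal").any()
    assert (t.status[: i + 1] == "optimal").all()


# ---------------------------------------------------------------------------
# optimised nodulation vs efficiency


@pytest.fixture(scope="module")
def opt_nodulation(holobiont_session):
    grid = np.arange(10.0, 111.0, 10.0)
    return {
        cap: ex.optimize_nodulation_curve(holobiont_session, grid, f_cap=cap).table
        for cap in (None, 0.10, 0.05)
    }


def test_capped_nodulation_never_beats_uncapped(opt_nodulation):
    free = opt_nodulation[None].growth_per_day.to_numpy()
    ten = opt_nodulation[0.10].growth_per_day.to_numpy()
    five = opt_nodulation[0.05].growth_per_day.to_numpy()
    tol = 1e-4  # inner golden-section search tolerance in f propagates here
    assert (five <= ten + tol).all()
    assert (ten <= free + tol).all()
    assert five[0] < ten[0] - tol  # the caps genuinely bind at low efficiency


def test_diminishing_returns_in_fixation_efficiency(opt_nodulation):
    t = opt_nodulation[None]
    g = t.set_index("efficiency").growth_per_day
    e_max = t.efficiency.max()
    e_half = t.efficiency.iloc[(t.efficiency - e_max / 2).abs().idxmin()]
    assert g[e_half] >= 0.85 * g[e_max]


def test_optimal_nodulation_shrinks_as_efficiency_rises(opt_nodulation):
    f_opt = opt_nodulation[None].f_opt.to_numpy()
    assert (np.diff(f_opt) <= 5e-3).all()  # non-increasing up to search tolerance
    assert f_opt[0] > 2 * f_opt[-1]


# ---------------------------------------------------------------------------
# cost decomposition


@pytest.fixture(scope="module")
def decomposition(holobiont_session):
    return ex.cost_decomposition(holobiont_session)


def test_relaxation_ordering_of_the_four_scenarios(decomposition):
    r1, r2, r3, r4 = decomposition.ratios
    assert r1 < r2 < r3 < r4 == 1.0


def test_cost_shares_partition_the_growth_gap(decomposition):
    shares = decomposition.shares
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v > 0 for v in shares.values())
    assert max(shares, key=shares.get) == "fixation_energy"


def test_share_arithmetic_on_reported_relative_growth_rates():
    # the published four-scenario relative growth rates 0.717 / 0.781 / 0.812
    # partition into ~67% fixation energy, ~22% maintenance, ~11% synthesis
    shares = ex.cost_shares_from_ratios(0.717, 0.781, 0.812)
    assert shares["fixation_energy"] == pytest.approx(0.664, abs=5e-4)
    assert shares["maintenance"] == pytest.approx(0.226, abs=5e-4)
    assert shares["synthesis"] == pytest.approx(0.110, abs=5e-4)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# carbon switch (sucrose vs dicarboxylates in zone III)


@pytest.fixture(scope="module")
def carbon_switch(sucrose_variant_holobiont):
    grid = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 5.0, 1000.0])
    return ex.carbon_switch_scan(sucrose_variant_holobiont, grid).table


def test_sucrose_and_dicarboxylates_substitute_monotonically(carbon_switch):
    t = carbon_switch  # sorted by ascending oxidase cap
    assert (np.diff(t.bacteroid_sucrose_uptake) >= -1e-6).all()
    assert (np.diff(t.bacteroid_dicarboxylate_uptake) <= 1e-6).all()
    assert (np.diff(t.growth_per_day) >= -1e-6).all()


def test_sucrose_extinct_below_a_sharp_threshold(carbon_switch):
    t = carbon_switch
    zero_sucrose = t[t.bacteroid_sucrose_uptake < 1e-6]
    assert len(zero_sucrose) > 0, "no sucrose-free regime found"
    assert (zero_sucrose.growth_per_day > 0).all()
    assert (zero_sucrose.bacteroid_dicarboxylate_uptake > 1e-3).all()
    assert t.bacteroid_sucrose_uptake.iloc[-1] > 1e-3


def test_sucrose_enabled_bacteroids_raise_plant_growth(
    holobiont_session, sucrose_variant_holobiont
):
    base = optimize_growth(holobiont_session).objective_value
    variant = optimize_growth(sucrose_variant_holobiont).objective_value
    assert variant > base * (1 + 1e-4)


# ---------------------------------------------------------------------------
# proton access


@pytest.fixture(scope="module")
def proton_report(plant, bacterium, calls):
    return ex.proton_access_test(plant, bacterium, calls=calls)


def test_dicarboxylate_use_requires_peribacteroid_protons(proton_report):
    assert proton_report["access_on"] > 1e-3
    assert proton_report["access_off"] == 0.0
    assert proton_report["access_off_status"] == "infeasible"


def test_access_on_build_equals_default_build(holobiont_session, proton_report):
    base = optimize_growth(holobiont_session).objective_value * 24.0
    assert proton_report["access_on"] == pytest.approx(base, rel=1e-6)


def test_forced_bacteroid_maintenance_keeps_access_off_infeasible_even_with_ammonium(
    plant, bacterium, calls
):
    report = ex.proton_access_test(plant, bacterium, calls=calls, nitrogen="ammonium")
    assert report["access_on"] > 1e-3
    assert report["access_off_status"] == "infeasible"


# ---------------------------------------------------------------------------
# substrate screen


def test_substrate_screen_calls(bacterium):
    table = ex.substrate_screen(bacterium.copy())
    calls = dict(zip(table.substrate, table.call))
    assert calls["glc"] == "growth"
    assert calls["succ"] == "growth"
    assert calls["xyl"] == "no-growth"
    assert calls["sucr"] == "no-growth"  # wild type lacks the sucrose pathway
    missing = ex.substrate_screen(bacterium.copy(), substrate_list=["ribose"])
    assert missing.call.iloc[0] == "untestable"


def test_headline_metrics_are_computed_and_sane(holobiont_session):
    metrics = ex.reference_metrics(holobiont_session)
    assert metrics["plant_growth_per_day"] > 0
    assert metrics["fixation_umol_h"] > 0
    assert 0 < metrics["carbon_cost_gC_per_gN"] < 20
    assert metrics["dicarboxylate_uptake_umol_h_per_g_bacteroid"] > 0


# ---------------------------------------------------------------------------
# CLI


def test_cli_build_is_deterministic(tmp_path):
    runner = CliRunner()
    outs = []
    for name in ("a", "b"):
        out = tmp_path / name
        result = runner.invoke(
            cli_main, ["build", "--toy", "--seed", "1", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        outs.append(
            (out / "reactions.tsv").read_bytes() + (out / "metabolites.tsv").read_bytes()
        )
    assert outs[0] == outs[1]


def test_cli_scan_emits_tabular_schema(tmp_path):
    runner = CliRunner()
    out = tmp_path / "scan.tsv"
    result = runner.invoke(
        cli_main, ["scan", "pareto_nodulation", "--toy",
                   "--efficiency", str(TOY_EFFICIENCY), "--out", str(out)]
    )
    assert result.exit_code == 0, result.output
    header = out.read_text().splitlines()[0].split("\t")
    assert {"f", "growth_per_day", "status"} <= set(header)


def test_cli_decompose_reports_ratios_and_shares():
    runner = CliRunner()
    result = runner.invoke(cli_main, ["decompose", "--toy"])
    assert result.exit_code == 0, result.output
    payload = json.loads(result.output)
    assert set(payload["ratios"]) == {
        "fixing_nodulated",
        "fixing_no_maintenance",
        "fixing_non_nodulated",
        "ammonium_non_nodulated",
    }
    assert set(payload["shares"]) == {"fixation_energy", "maintenance", "synthesis"}


def test_cli_delete_reports_lethal_and_neutral_genes():
    runner = CliRunner()
    result = runner.invoke(
        cli_main, ["delete", "bg_nifH", "bg_glnA", "--toy"]
    )
    assert result.exit_code == 0, result.output
    lines = {l.split("\t")[0]: l.split("\t") for l in result.output.strip().splitlines()[1:]}
    assert float(lines["bg_nifH"][3]) < 1e-9
    assert float(lines["bg_glnA"][3]) > 1e-3
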