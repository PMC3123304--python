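"""Gating and combinatorial decoding of flow-cytometry event tables."""

import numpy as np
import pandas as pd
import pytest

from mihakit.flow import (
    GatingConfig,
    decode_events,
    dual_color_frequency,
    format_frequency,
    gate_cd8,
    read_events,
    read_gating_config,
    write_events,
)
from mihakit.simulate import FlowSimConfig, SimulationConfig, simulate_events

NEG, POS = 10.0, 50_000.0


def make_events(panel, n, positives=None):
    """All-negative table of n events (gated-eligible) with optional
    per-row positive channels: positives = {row_index: [channels...]}."""
    channels = list(panel.fluorochromes.channels)
    df = pd.DataFrame(NEG, index=range(n),
                      columns=channels + ["dump_intensity", "viability_intensity"])
    df["cd8_intensity"] = POS
    for i, chans in (positives or {}).items():
        for ch in chans:
            df.loc[i, ch] = POS
    return df


def linear_gates(panel):
    thr = {ch: 1000.0 for ch in panel.fluorochromes.channels}
    thr.update({"cd8_intensity": 1000.0, "dump_intensity": 1000.0,
                "viability_intensity": 1000.0})
    return GatingConfig(thresholds=thr)


def test_gate_keeps_all_when_all_live_dumpneg_cd8(reference_panel):
    events = make_events(reference_panel, 50)
    cfg = linear_gates(reference_panel)
    gated = gate_cd8(events, cfg)
    assert len(gated) == 50
    assert gated.attrs["gate_counts"]["live"] == 50


def test_gate_drops_dead_dump_positive_and_cd8_negative(reference_panel):
    events = make_events(reference_panel, 4)
    cfg = linear_gates(reference_panel)
    events.loc[0, "viability_intensity"] = POS  # dead
    events.loc[1, "dump_intensity"] = POS       # lineage dump
    events.loc[2, "cd8_intensity"] = NEG        # not CD8
    gated = gate_cd8(events, cfg)
    assert list(gated.index) == [3]
    counts = gated.attrs["gate_counts"]
    assert (counts["total"], counts["live"], counts["live_dump_neg"],
            counts["live_dump_neg_cd8_pos"]) == (4, 3, 2, 1)


def test_all_dead_gives_empty_subset(reference_panel):
    events = make_events(reference_panel, 10)
    events["viability_intensity"] = POS
    assert len(gate_cd8(events, linear_gates(reference_panel))) == 0


def test_missing_gating_column_is_named(reference_panel):
    events = make_events(reference_panel, 3).drop(columns=["dump_intensity"])
    with pytest.raises(KeyError, match="dump_intensity"):
        gate_cd8(events, linear_gates(reference_panel))


def test_gated_cd8_fraction_matches_generator_truth(reference_panel, base_seed):
    cfg = SimulationConfig(seed=base_seed,
                           flow=FlowSimConfig(n_events=30_000, cd8_fraction=0.70))
    res = simulate_events(cfg, reference_panel)
    gated = gate_cd8(res.events, res.gating)
    eligible = int((res.truth["is_dump_neg"]).sum())
    frac = len(gated) / eligible
    se = np.sqrt(0.70 * 0.30 / eligible)
    assert abs(frac - 0.70) < 3 * se


def test_no_positive_events_decode_to_zero_everywhere(reference_panel):
    events = make_events(reference_panel, 100)
    cfg = linear_gates(reference_panel)
    result = decode_events(gate_cd8(events, cfg), reference_panel, cfg)
    assert all(v == 0.0 for v in result.frequencies.values())
    assert result.n_negative == 100


def test_pe_apc_dual_positive_event_assigns_to_smcy(reference_panel):
    events = make_events(reference_panel, 10, positives={0: ["PE", "APC"]})
    cfg = linear_gates(reference_panel)
    result = decode_events(gate_cd8(events, cfg), reference_panel, cfg)
    assert result.assigned_counts["SMCY.A2"] == 1
    assert result.frequencies["SMCY.A2"] == pytest.approx(10.0)
    assert result.assignments.iloc[0] == "SMCY.A2"


def test_single_triple_and_unmatched_events_are_excluded(reference_panel):
    chans = list(reference_panel.fluorochromes.channels)
    events = make_events(
        reference_panel, 6,
        positives={0: chans[:1], 1: chans[:3], 2: chans[:4], 3: chans},
    )
    cfg = linear_gates(reference_panel)
    result = decode_events(gate_cd8(events, cfg), reference_panel, cfg)
    assert result.n_unassigned_single == 1
    assert result.n_unassigned_multi == 3
    assert result.n_negative == 2
    assert sum(result.assigned_counts.values()) == 0


def test_decode_conservation_invariant(reference_panel, base_seed):
    cfg = SimulationConfig(
        seed=base_seed,
        flow=FlowSimConfig(n_events=20_000,
                           spike_frequencies={"SMCY.A2": 0.01, "HA-2.A2": 0.003}),
    )
    res = simulate_events(cfg, reference_panel)
    gated = gate_cd8(res.events, res.gating)
    result = decode_events(gated, reference_panel, res.gating)
    total = (sum(result.assigned_counts.values()) + result.n_unassigned_single
             + result.n_unassigned_multi + result.n_negative)
    assert total == result.n_cd8_gated == len(gated)
    # each event maps to at most one label
    assert len(result.assignments) == len(gated)


def test_dual_color_readout_11_in_10000_is_011_percent(reference_panel):
    # mirrors the precision of a 0.11% dual-color tetramer readout
    positives = {i: ["PE", "Qdot605"] for i in range(11)}
    events = make_events(reference_panel, 10_000, positives=positives)
    cfg = linear_gates(reference_panel)
    gated = gate_cd8(events, cfg)
    pct = dual_color_frequency(gated, frozenset(("PE", "Qdot605")), cfg)
    assert pct == pytest.approx(0.11)
    assert format_frequency(pct) == "0.11%"


def test_dual_color_is_never_below_decoded_frequency(reference_panel, base_seed):
    cfg = SimulationConfig(
        seed=base_seed,
        flow=FlowSimConfig(n_events=30_000,
                           spike_frequencies={"SMCY.A2": 0.01},
                           single_noise_rate=0.02, triple_noise_rate=0.01),
    )
    res = simulate_events(cfg, reference_panel)
    gated = gate_cd8(res.events, res.gating)
    decoded = decode_events(gated, reference_panel, res.gating)
    for pid, code in reference_panel.entries.items():
        dual = dual_color_frequency(gated, code, res.gating)
        assert dual >= decoded.frequencies[pid] - 1e-12


def test_raising_a_threshold_never_increases_positive_count(reference_panel, base_seed):
    cfg = SimulationConfig(seed=base_seed, flow=FlowSimConfig(n_events=5_000))
    res = simulate_events(cfg, reference_panel)
    ch = "PE"
    counts = []
    for thr in (10.0, 100.0, 1000.0, 10_000.0, 100_000.0):
        g = GatingConfig(thresholds={**res.gating.thresholds, ch: thr})
        counts.append(int(g.is_positive(res.events, ch).sum()))
    assert counts == sorted(counts, reverse=True)


def test_format_frequency_reporting_convention():
    assert format_frequency(0.0) == "0.00%"
    assert format_frequency(0.005) == "<0.01%"
    assert format_frequency(0.11) == "0.11%"
    assert format_frequency(1.276) == "1.28%"


def test_transforms_and_negative_control_thresholding(reference_panel):
    rng = np.random.default_rng(8)
    negatives = pd.DataFrame({"PE": rng.lognormal(4, 0.4, 5000)})
    cfg = GatingConfig.from_negative_control(negatives, ["PE"], quantile=0.999,
                                             transform="asinh", cofactor=150.0)
    assert cfg.threshold_mode == "quantile-of-negatives"
    # ~0.1% of the negative control exceeds its own 99.9th percentile
    frac = cfg.is_positive(negatives, "PE").mean()
    assert frac <= 0.002
    with pytest.raises(ValueError):
        GatingConfig(thresholds={}, transform="biexponential")
    with pytest.raises(ValueError):
        GatingConfig(thresholds={}, transform="asinh", cofactor=0.0)
    log_cfg = GatingConfig(thresholds={"PE": 3.0}, transform="log")
    assert (log_cfg.apply_transform(np.array([1000.0])) == 3.0).all()


def test_event_table_io_and_gating_yaml(tmp_path, reference_panel):
    events = make_events(reference_panel, 5, positives={0: ["PE", "APC"]})
    path = tmp_path / "events.tsv"
    write_events(events, path)
    back = read_events(path)
    assert list(back.columns) == list(events.columns)
    assert np.allclose(back.to_numpy(), events.to_numpy())

    yml = tmp_path / "gates.yaml"
    yml.write_text(
        "transform: linear\ncofactor: 150\nthresholds:\n  PE: 1000\n  APC: 1000\n"
    )
    cfg = read_gating_config(yml)
    assert cfg.threshold_for("PE") == 1000.0

    bad = tmp_path / "bad.tsv"
    bad.write_text("PE\tAPC\n1.0\tinf\n")
    with pytest.raises(ValueError, match="finite"):
        read_events(bad)
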