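"""Pair geometry, continuity, and the constant-curvature contour search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import chain_coordinates, oracle_chains, structured_edge_field
from curvestats._angles import wrap90
from curvestats.mapping import (
    PairGeometry,
    bin_contours,
    curvature_class,
    extract_all_end_elements,
    extract_end_elements,
    find_contours,
    is_continuous,
    length_bin_label,
    pair_geometry,
)


def edge(x, y, o):
    return {"x_px": x, "y_px": y, "orientation_deg": o}


class TestPairGeometry:
    def test_collinear_pair(self):
        g = pair_geometry(edge(0, 0, 0), edge(10, 0, 0))
        assert g.d == pytest.approx(10.0)
        assert g.phi == pytest.approx(0.0)
        assert g.theta == pytest.approx(0.0)
        assert is_continuous(g)

    def test_cocircular_pair_theta_twice_phi(self):
        # direction 15 deg off the first orientation, orientations 30 apart
        b = edge(10 * np.cos(np.deg2rad(15)), 10 * np.sin(np.deg2rad(15)), 30.0)
        g = pair_geometry(edge(0, 0, 0), b)
        assert g.phi == pytest.approx(15.0)
        assert g.theta == pytest.approx(30.0)
        assert is_continuous(g, tol_deg=5)

    def test_coincident_elements_rejected(self):
        with pytest.raises(ValueError):
            pair_geometry(edge(1, 1, 0), edge(1, 1, 90))

    @given(st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_swap_preserves_distance_and_continuity_defect(self, seed):
        rng = np.random.default_rng(seed)
        a = edge(*rng.uniform(0, 100, 2), rng.uniform(0, 180))
        b = edge(*rng.uniform(0, 100, 2), rng.uniform(0, 180))
        gab, gba = pair_geometry(a, b), pair_geometry(b, a)
        assert gab.d == pytest.approx(gba.d)
        assert gab.continuity_defect_deg == pytest.approx(
            gba.continuity_defect_deg, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_swap_negates_angles_for_continuous_pairs(self, seed):
        # construct an exactly cocircular pair, then swap
        rng = np.random.default_rng(seed)
        o0 = rng.uniform(0, 180)
        step = rng.uniform(-80, 80)
        chain = chain_coordinates(step, rng.uniform(5, 30), 2,
                                  start=rng.uniform(0, 100, 2), start_orient=o0)
        a, b = chain.iloc[0], chain.iloc[1]
        gab, gba = pair_geometry(a, b), pair_geometry(b, a)
        assert gba.theta == pytest.approx(-wrap90(gab.theta), abs=1e-6)
        assert wrap90(gba.phi) == pytest.approx(-wrap90(gab.phi), abs=1e-6)


class TestContinuity:
    @pytest.mark.parametrize("phi,theta,expected", [
        (0.0, 0.0, True),
        (10.0, 20.0, True),      # exterior-angle rule
        (0.0, 30.0, False),      # |30 - 0| > 5
        (15.0, 27.0, True),      # within the 5 deg tolerance
        (15.0, 36.1, False),
    ])
    def test_exterior_angle_rule(self, phi, theta, expected):
        assert is_continuous(PairGeometry(10.0, phi, theta), tol_deg=5) is expected


class TestFindContours:
    def test_planted_chain_recovered_exactly(self):
        df = chain_coordinates(20.0, 20.0, 4, start=(50, 60), start_orient=10)
        out = find_contours(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert set(row["members"]) == {0, 1, 2, 3}
        assert row["step_deg"] == pytest.approx(20.0, abs=1e-6)
        assert row["spacing_px"] == pytest.approx(20.0, abs=1e-6)

    def test_straight_chain_has_zero_step(self):
        df = chain_coordinates(0.0, 15.0, 4, start_orient=37.0)
        out = find_contours(df)
        assert len(out) == 1
        assert out.iloc[0]["step_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_perturbed_spacing_rejected(self):
        df = chain_coordinates(20.0, 20.0, 4)
        # push the third element along the 2->3 displacement by > d/5
        dx = df.loc[2, "x_px"] - df.loc[1, "x_px"]
        dy = df.loc[2, "y_px"] - df.loc[1, "y_px"]
        df.loc[2, "x_px"] += dx / 20.0 * 4.5
        df.loc[2, "y_px"] += dy / 20.0 * 4.5
        out = find_contours(df)
        assert len(out) == 0
        assert len(oracle_chains(df)) == 0  # agreement with brute force

    def test_fewer_than_four_edges_is_empty(self):
        df = chain_coordinates(10.0, 20.0, 3)
        assert len(find_contours(df)) == 0

    def test_no_edge_in_two_contours(self):
        rng = np.random.default_rng(42)
        df = structured_edge_field(rng, n_chains=4, n_noise=30)
        out = find_contours(df)
        members = [m for _, row in out.iterrows() for m in row["members"]]
        assert len(members) == len(set(members))

    def test_horizontal_reflection_negates_step(self):
        rng = np.random.default_rng(5)
        df = structured_edge_field(rng, n_chains=4, n_noise=10,
                                   jitter=0.3, orient_jitter=1.0)
        out = find_contours(df)
        mirrored = df.copy()
        mirrored["x_px"] = -mirrored["x_px"]
        mirrored["orientation_deg"] = (180.0 - mirrored["orientation_deg"]) % 180.0
        out_m = find_contours(mirrored)
        assert len(out) == len(out_m) > 0
        steps = sorted(round(s, 6) for s in out["step_deg"])
        steps_m = sorted(round(-s, 6) for s in out_m["step_deg"])
        assert steps == steps_m

    def test_greedy_results_lie_in_oracle_solution_set(self):
        total = 0
        for trial in range(60):
            rng = np.random.default_rng(trial)
            df = structured_edge_field(rng)
            sols = oracle_chains(df)
            found = find_contours(df)
            total += len(found)
            for _, row in found.iterrows():
                assert tuple(int(m) for m in row["members"]) in sols
        assert total > 10  # the check has teeth

    def test_planted_chains_always_recovered_in_noise(self):
        hits = 0
        trials = 100
        for trial in range(trials):
            rng = np.random.default_rng(10_000 + trial)
            step = float(rng.choice([0, 10, 20, 30, 40]) * rng.choice([-1, 1]))
            spacing = float(rng.uniform(10, 30))
            chain = chain_coordinates(step, spacing, 4, start=rng.uniform(40, 80, 2),
                                      start_orient=float(rng.uniform(0, 180)))
            pts = chain[["x_px", "y_px"]].to_numpy()
            noise = rng.uniform(0, 400, (80, 2))
            dmin = np.hypot(noise[:, None, 0] - pts[None, :, 0],
                            noise[:, None, 1] - pts[None, :, 1]).min(axis=1)
            noise = noise[dmin > 3 * spacing][:20]
            df = pd.concat([chain, pd.DataFrame({
                "x_px": noise[:, 0], "y_px": noise[:, 1],
                "orientation_deg": rng.uniform(0, 180, len(noise))})],
                ignore_index=True)
            out = find_contours(df)
            hits += any(set(int(m) for m in row["members"]) == {0, 1, 2, 3}
                        and abs(abs(row["step_deg"]) - abs(step)) <= 5
                        for _, row in out.iterrows())
        assert hits == trials


class TestEndElements:
    @pytest.mark.parametrize("rho", range(-30, 61, 10))
    def test_planted_continuation_recovered(self, rho):
        # a 5th element continuing the chain at relative orientation rho
        step = 20.0
        df = chain_coordinates(step, 20.0, 4, start=(100, 100), start_orient=10)
        tail = df.iloc[3]
        e_or = tail["orientation_deg"] + rho
        theta = wrap90(e_or - tail["orientation_deg"])
        prev = df.iloc[2]
        outward = np.degrees(np.arctan2(tail["y_px"] - prev["y_px"],
                                        tail["x_px"] - prev["x_px"]))
        direction = tail["orientation_deg"] + theta / 2.0
        if np.cos(np.deg2rad(direction - outward)) < 0:
            direction += 180.0
        df = pd.concat([df, pd.DataFrame([{
            "x_px": tail["x_px"] + 20 * np.cos(np.deg2rad(direction)),
            "y_px": tail["y_px"] + 20 * np.sin(np.deg2rad(direction)),
            "orientation_deg": e_or % 180.0}])], ignore_index=True)
        contours = find_contours(df.iloc[:4])
        ends = extract_all_end_elements(contours, df)
        tail_recs = ends[ends["end"] == "tail"]
        assert len(tail_recs) == 1
        assert tail_recs["orientation_rel_deg"].iloc[0] == pytest.approx(rho, abs=1e-6)

    def test_backward_candidate_excluded_by_direction_window(self):
        # a candidate at 120 deg from the terminal's outward direction folds
        # back over the contour and must be ignored
        df = chain_coordinates(0.0, 20.0, 4, start=(100, 100), start_orient=0)
        back = {"x_px": df.iloc[3]["x_px"] + 20 * np.cos(np.deg2rad(120)),
                "y_px": df.iloc[3]["y_px"] + 20 * np.sin(np.deg2rad(120)),
                "orientation_deg": 60.0}
        full = pd.concat([df, pd.DataFrame([back])], ignore_index=True)
        contours = find_contours(df)
        ends = extract_end_elements(contours.iloc[0], full)
        assert not ((ends["end"] == "tail") & (ends["edge_index"] == 4)).any()

    def test_collinear_continuation_reads_zero(self):
        df = chain_coordinates(0.0, 20.0, 5, start_orient=45.0)
        contours = find_contours(df.iloc[:4])
        ends = extract_all_end_elements(contours, df)
        tail = ends[ends["end"] == "tail"]
        assert len(tail) == 1
        assert tail["orientation_rel_deg"].iloc[0] == pytest.approx(0.0, abs=1e-9)


class TestBinning:
    @pytest.mark.parametrize("spacing,label", [
        (8.0, "1-8"), (20.0, "18-24"), (9.0, "9-17"), (33.4, "25-33"),
        (42.0, "34-42"), (0.4, "unbinned"), (48.0, "unbinned"),
    ])
    def test_length_bins_use_printed_edges(self, spacing, label):
        assert length_bin_label(spacing) == label

    @pytest.mark.parametrize("step,cls", [(0, 0), (12, 10), (-21, 20), (38, 40)])
    def test_curvature_class_rounds_to_nearest_ten(self, step, cls):
        assert curvature_class(step) == cls

    def test_empty_input_gives_all_zero_table(self):
        table = bin_contours(pd.DataFrame(columns=["step_deg", "spacing_px"]))
        assert (table.to_numpy() == 0).all()

    def test_counts_conserved_against_occurrence(self):
        from curvestats.stats import occurrence_by_curvature

        rng = np.random.default_rng(8)
        frames = [find_contours(structured_edge_field(rng)) for _ in range(5)]
        contours = pd.concat([f for f in frames if len(f)], ignore_index=True)
        contours["curvature_class_deg"] = contours["step_deg"].map(curvature_class)
        table = bin_contours(contours)
        counts = occurrence_by_curvature(contours)
        binned = table.drop(columns="unbinned").sum(axis=1)
        assert (counts == binned.loc[counts.index]).all()
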