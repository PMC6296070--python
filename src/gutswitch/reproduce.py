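"""End-to-end driver assembling every published analysis in one report.

Runs, in order: equilibrium location at the reference lumen butyrate
level, lumen-butyrate continuation with fold normal forms, lumen-LPS
continuation, the pulse switching experiment, the extended-model
continuation, the hysteresis density transform, and the invariance
checks.  Independent stages continue past failures of earlier ones;
failures are flagged in the report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .bimodality import InputDensity, transform_density
from .config import write_json
from .continuation import trace_branch
from .dynamics import PulseProtocol, classify_endpoint, simulate
from .equilibria import InvariantBox, find_fixed_points, verify_box_invariance
from .model import ModelParameters, preset

log = logging.getLogger("gutswitch")

__all__ = ["reproduce_paper"]

#: the reference operating point: lumen butyrate around the bistable middle
K_BO_REFERENCE = 130.0
#: pulse protocol with the published nominal amplitudes.  The nominal high
#: amplitude 200 sits 0.06% BELOW the computed fold at k_Bo = 200.1167, so
#: under exact integration this protocol does not switch the system.
SWITCH_PROTOCOL_NOMINAL = PulseProtocol(
    baseline=130.0, segments=((50.0, 170.0, 200.0), (200.0, 270.0, 50.0))
)
#: the same protocol with the high pulse raised just past the fold, which
#: completes the two-way switch within the pulse durations
SWITCH_PROTOCOL = PulseProtocol(
    baseline=130.0, segments=((50.0, 170.0, 205.0), (200.0, 270.0, 50.0))
)


def reproduce_paper(
    outdir,
    params: ModelParameters | None = None,
    *,
    seed: int = 0,
) -> dict:
    """Run the full analysis suite and write CSV artifacts plus a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = (params or preset("fig2a")).with_(k_Bo=K_BO_REFERENCE)
    report: dict = {"seed": seed, "failures": []}

    def stage(name, fn):
        log.info("stage: %s", name)
        try:
            report[name] = fn()
        except Exception as exc:  # keep independent stages running
            log.exception("stage %s failed", name)
            report["failures"].append({"stage": name, "error": str(exc)})

    # 1. equilibria at the reference point
    def _equilibria():
        fps = find_fixed_points(p, "core")
        write_json([fp.to_dict() for fp in fps], outdir / "equilibria_kBo130.json")
        return {
            "count": len(fps),
            "stability": [fp.stability for fp in fps],
            "B_values": [float(fp.state[-1]) for fp in fps],
        }

    stage("equilibria", _equilibria)

    # 2. lumen-butyrate continuation with folds and normal forms
    branch_core = None

    def _continuation_kBo():
        nonlocal branch_core
        branch_core = trace_branch(p, "core", "k_Bo", (10.0, 300.0))
        branch_core.to_csv(outdir / "branch_core_kBo.csv")
        write_json([f.to_dict() for f in branch_core.folds], outdir / "folds_core_kBo.json")
        return {
            "n_folds": len(branch_core.folds),
            "fold_params": [float(f.param) for f in branch_core.folds],
            "normal_form_a": [float(f.a) for f in branch_core.folds],
            "hopf_candidates": branch_core.hopf_candidates,
        }

    stage("continuation_kBo", _continuation_kBo)

    # 3. lumen-LPS continuation (one-way switch)
    def _continuation_kbl():
        branch = trace_branch(p, "core", "k_bl", (0.0, 50.0))
        branch.to_csv(outdir / "branch_core_kbl.csv")
        write_json([f.to_dict() for f in branch.folds], outdir / "folds_core_kbl.json")
        return {
            "n_folds": len(branch.folds),
            "fold_params": [float(f.param) for f in branch.folds],
        }

    stage("continuation_kbl", _continuation_kbl)

    # 4. pulse switching experiment: nominal amplitudes and just-past-fold
    def _pulse():
        fps = find_fixed_points(p, "core")
        stable = [fp for fp in fps if fp.stability == "stable"]
        inflamed, healthy = stable[0], stable[-1]
        labels = {0: "inflamed", 1: "non_inflamed", "unresolved": "unresolved"}
        out = {}
        for tag, protocol in (
            ("nominal", SWITCH_PROTOCOL_NOMINAL),
            ("above_fold", SWITCH_PROTOCOL),
        ):
            traj = simulate(inflamed.state, p, "core", (0.0, 350.0), protocol)
            traj.to_csv(outdir / f"pulse_trajectory_{tag}.csv")
            after_high = classify_endpoint(_truncate(traj, 199.0), [inflamed, healthy])
            after_low = classify_endpoint(traj, [inflamed, healthy])
            out[tag] = {
                "high_pulse_amplitude": protocol.segments[0][2],
                "after_high_pulse": labels[after_high],
                "final": labels[after_low],
                "switches_both_ways": after_high == 1 and after_low == 0,
            }
        return out

    stage("pulse_switching", _pulse)

    # 5. extended-model continuation (broadened bistable window)
    def _extended():
        branch = trace_branch(p, "extended", "k_Bo", (10.0, 300.0))
        branch.to_csv(outdir / "branch_extended_kBo.csv")
        return {
            "n_folds": len(branch.folds),
            "fold_params": [float(f.param) for f in branch.folds],
        }

    stage("continuation_extended", _extended)

    # 6. density transform through the hysteresis
    def _transform():
        if branch_core is None:
            raise RuntimeError("continuation_kBo stage did not produce a branch")
        dens = InputDensity(mean=130.0, sd=40.0)
        dt = transform_density(branch_core, dens)
        dt.to_csv(outdir / "density_transform.csv")
        write_json(dt.summary(), outdir / "density_summary.json")
        return {"n_modes": len(dt.modes()), "retained_mass": dt.retained_mass}

    stage("density_transform", _transform)

    # 7. invariance checks
    def _verify():
        rng = np.random.default_rng(seed)
        box_report = verify_box_invariance(p, "core", InvariantBox(), 200, rng=rng)
        return {
            "box_passed": box_report.passed,
            "origin_ball_ok": box_report.origin_ball_ok,
            "faces": [
                {"face": f.face, "passed": f.passed, "worst_margin": f.worst_margin}
                for f in box_report.faces
            ],
        }

    stage("verify", _verify)

    write_json(report, outdir / "report.json")
    return report


def _truncate(traj, t_end: float):
    """View of a trajectory up to time t_end (inclusive)."""
    from .dynamics import Trajectory

    keep = traj.t <= t_end + 1e-9
    return Trajectory(
        t=traj.t[keep],
        states=traj.states[keep],
        k_Bo_applied=traj.k_Bo_applied[keep],
        variant=traj.variant,
    )
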