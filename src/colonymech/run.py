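"""Run orchestration: confined equilibration, release, and analysis.

A run has two phases.  Phase 1 evolves vertex positions and polarity under
circular confinement until the colony settles (displacement tolerance or a
step cap).  Phase 2 removes the confinement and lets the colony break
symmetry; in the ``stretching`` scenario the stretch-alignment torque
turns polarities toward the x axis and the reference angle for Q is 0,
otherwise the reference is the final colony angle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .kinematics import (
    EllipseFit,
    TrackedFrames,
    decompose_shear,
    project_xx,
    shape_Q,
    _ellipse_from_moments,
)
from .fixtures import frames_from_mesh
from .mesh import TissueMesh, build_disc_colony
from .model import ModelParams, step, total_forces
from .nematic import NematicSummary, fold_nematic_difference
from .polarity import AlignmentParams, PolarityField, init_polarity_two_defects, update_polarity

SCENARIOS = ("free-spreading", "stretching")


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation run."""

    n_cells: int = 120
    scenario: str = "free-spreading"
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    align: AlignmentParams = field(default_factory=AlignmentParams)
    # defect spec for the initial polarity: charges and positions in units
    # of the colony radius (scaled at build time)
    defect_charges: tuple = (0.5, 0.5)
    defect_positions: tuple = ((-0.5, 0.0), (0.5, 0.0))
    alpha0: float = 0.0
    t_equil: float = 15.0
    t_run: float = 10.0
    equil_tol: float = 1e-4
    n_frames: int = 11
    boundary_segments: int = 256
    lloyd_iterations: int = 40

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if isinstance(self.params, dict):
            self.params = ModelParams(**self.params)
        if isinstance(self.align, dict):
            self.align = AlignmentParams(**self.align)
        # normalize sequence fields so YAML round-trips are the identity
        self.defect_charges = tuple(float(k) for k in self.defect_charges)
        self.defect_positions = tuple(
            (float(x), float(y)) for x, y in self.defect_positions
        )

    @property
    def stretching(self) -> bool:
        return self.scenario == "stretching"

    @property
    def radius(self) -> float:
        """Colony radius so that cells have unit mean area."""
        return float(np.sqrt(self.n_cells / np.pi))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["align"] = asdict(self.align)
        d["defect_charges"] = list(self.defect_charges)
        d["defect_positions"] = [list(p) for p in self.defect_positions]
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def free_spreading_preset(
    seed: int,
    n_cells: int = 120,
    sigma_a_prime: float = -5.0,
    lam_prime: float = 20.0,
    t_run: float = 15.0,
    t_equil: float = 30.0,
) -> RunConfig:
    """Free-spreading scenario: extensile stress with biased edge tension.

    Defaults are the colony-spreading parameter set (sigma_a' = -5,
    lambda' = 20) with a two-(+1/2)-defect initial polarity.  The long
    confined phase lets cell shapes relax onto the polarity pattern (the
    tension-network shear time is ~ gamma sqrt(A0)/Lambda = 10 time
    units), so the t0 mean shape nematic is a faithful readout of p.
    """
    cfg = RunConfig(
        n_cells=n_cells,
        scenario="free-spreading",
        seed=seed,
        t_run=t_run,
        t_equil=t_equil,
        boundary_segments=180,
        lloyd_iterations=20,
    )
    cfg.params = ModelParams.from_primed(
        sigma_a_prime=sigma_a_prime, lam_prime=lam_prime, confine_radius=cfg.radius
    )
    return cfg


def stretching_preset(
    seed: int,
    sigma_a_prime: float,
    lam_prime: float,
    n_cells: int = 120,
    t_run: float = 20.0,
) -> RunConfig:
    """Uniaxial-stretching scenario: the stretch-alignment torque turns
    polarities toward x after release and the active stress is contractile
    (sigma_a' > 0, cells elongate perpendicular to p).

    (sigma_a' = 2, lambda' = 50) gives collective elongation along x via
    T1s; (sigma_a' = 4, lambda' = 25) elongates perpendicular to x via
    single-cell elongation.
    """
    cfg = RunConfig(
        n_cells=n_cells,
        scenario="stretching",
        seed=seed,
        t_run=t_run,
        boundary_segments=180,
        lloyd_iterations=20,
    )
    cfg.params = ModelParams.from_primed(
        sigma_a_prime=sigma_a_prime, lam_prime=lam_prime, confine_radius=cfg.radius
    )
    return cfg


@dataclass
class RunRecord:
    config_hash: str
    package_version: str
    seeds: dict
    n_t1_events: int
    n_frames: int
    manifest: list


@dataclass
class SimulationResult:
    """In-memory trajectory: mesh snapshots, tracked frames, event log."""

    config: RunConfig
    record: RunRecord
    snapshots: list  # (time, vertices copy, cell loops copy)
    tracked: TrackedFrames
    events: list
    polarity: PolarityField
    mesh: TissueMesh  # final state
    initial_mesh: TissueMesh


def _substreams(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    mesh_s, signs_s, noise_s = (int(s) % (2**31) for s in ss.generate_state(3))
    return {"mesh": mesh_s, "polarity_signs": signs_s, "noise": noise_s}


def run_simulation(config: RunConfig, outdir=None) -> SimulationResult:
    """Execute both phases and (optionally) export trajectory files."""
    seeds = _substreams(config.seed)
    params = config.params
    R = config.radius
    # confinement at the built colony radius
    params.confine_radius = R
    mesh = build_disc_colony(
        config.n_cells,
        R,
        seed=seeds["mesh"],
        n_lloyd=config.lloyd_iterations,
        boundary_segments=config.boundary_segments,
    )
    charges = np.asarray(config.defect_charges, dtype=float)
    positions = R * np.asarray(config.defect_positions, dtype=float).reshape(-1, 2)
    pol = init_polarity_two_defects(mesh, charges, positions, config.alpha0, seeds["polarity_signs"])
    rng = np.random.default_rng(seeds["noise"])

    events: list = []

    def advance(duration: float, confined: bool, stretching: bool, tol: float | None):
        t_end = mesh.time + duration
        guard = 0
        while mesh.time < t_end - 1e-12:
            update_polarity(mesh, pol, config.align, params.dt, stretching=stretching, rng=rng)
            dt, ev, max_disp = step(mesh, pol, params, confined=confined)
            events.extend(ev)
            if tol is not None and not ev and max_disp < tol * params.eps_cls:
                break
            guard += 1
            if guard > 2_000_000:
                raise RuntimeError("step budget exhausted")

    # phase 1: confined equilibration (no stretch torque yet)
    advance(config.t_equil, confined=True, stretching=False, tol=config.equil_tol)
    initial_mesh = mesh.copy()
    t0 = mesh.time

    # phase 2: release, record frames at a fixed cadence
    frame_times = t0 + np.linspace(0.0, config.t_run, config.n_frames)
    snapshots = []
    frames = []
    times = []

    def record():
        snapshots.append((mesh.time, mesh.vertices.copy(), [c.copy() for c in mesh.cells]))
        frames.append(frames_from_mesh(mesh))
        times.append(mesh.time - t0)

    record()
    for target in frame_times[1:]:
        while mesh.time < target - 1e-12:
            update_polarity(
                mesh, pol, config.align, params.dt, stretching=config.stretching, rng=rng
            )
            _, ev, _ = step(mesh, pol, params, confined=False)
            events.extend(ev)
        record()

    # tag T2-removed cells as extruded in the last frame they appear, so the
    # shear decomposition attributes their disappearance correctly
    for k in range(len(frames) - 1):
        lost = set(map(int, frames[k].ids)) - set(map(int, frames[k + 1].ids))
        for cid in lost:
            frames[k].tags[cid] = "extruded"

    tracked = TrackedFrames(times=np.array(times), frames=frames)
    record_obj = RunRecord(
        config_hash=config.hash(),
        package_version=_version(),
        seeds=seeds,
        n_t1_events=len(events),
        n_frames=len(frames),
        manifest=[],
    )
    result = SimulationResult(
        config=config,
        record=record_obj,
        snapshots=snapshots,
        tracked=tracked,
        events=events,
        polarity=pol,
        mesh=mesh,
        initial_mesh=initial_mesh,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.save_mesh(outdir / "final_mesh.json", mesh, polarity=pol, params=params, events=events)
        cio.save_tracked_frames(outdir / "tracked_cells.csv", tracked)
        cio.save_config(outdir / "config.yaml", config.to_dict())
        record_obj.manifest = ["final_mesh.json", "tracked_cells.csv", "config.yaml"]
        (outdir / "run_record.json").write_text(json.dumps(asdict(record_obj), indent=1))
    return result


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("colonymech")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def colony_moment_ellipse(vertices: np.ndarray, cells: list) -> EllipseFit:
    """Moment-equivalent ellipse of the whole colony region.

    Cells tile the colony, so the region's second central moments are the
    area-weighted combination of per-cell moments plus the parallel-axis
    terms; no pixelization or polygon union is needed.
    """
    from .mesh import polygon_moment_tensor

    A_tot = 0.0
    C = np.zeros(2)
    parts = []
    for loop in cells:
        if len(loop) < 3:  # removed cell placeholder
            continue
        pts = vertices[loop]
        x, y = pts[:, 0], pts[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        A = 0.5 * np.sum(cross)
        cx = np.sum((x + xn) * cross) / (6 * A)
        cy = np.sum((y + yn) * cross) / (6 * A)
        M = polygon_moment_tensor(pts)
        parts.append((A, np.array([cx, cy]), M))
        A_tot += A
        C += A * np.array([cx, cy])
    C /= A_tot
    Mtot = np.zeros((2, 2))
    for A, c, M in parts:
        d = c - C
        Mtot += A * (M + np.outer(d, d))
    Mtot /= A_tot
    return _ellipse_from_moments(Mtot, C)


@dataclass
class ShapeTensorSeries:
    """Colony Q tensor time series relative to a reference angle."""

    times: np.ndarray
    Q_xx: np.ndarray
    Q_xy: np.ndarray
    alpha_ref: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "Q_xx": self.Q_xx, "Q_xy": self.Q_xy})


def shape_series_from_snapshots(snapshots, alpha_ref: float | None = None) -> ShapeTensorSeries:
    """Ellipse-fit Q series; ``alpha_ref=None`` uses the final colony angle."""
    fits = [colony_moment_ellipse(v, c) for (_, v, c) in snapshots]
    if alpha_ref is None:
        alpha_ref = fits[-1].theta
    Q = np.array([shape_Q(f, alpha_ref) for f in fits])
    times = np.array([t for (t, _, _) in snapshots])
    return ShapeTensorSeries(times=times, Q_xx=Q[:, 0], Q_xy=Q[:, 1], alpha_ref=alpha_ref)


def mesh_mean_nematic(vertices: np.ndarray, cells: list) -> tuple[float, float]:
    """Area-weighted mean cell-shape nematic (angle, magnitude) of a tiling."""
    from .mesh import TissueMesh

    m = TissueMesh(vertices, cells)
    qs, _ = m.all_cell_nematics()
    A = m.cell_areas()
    q = (A[:, None] * qs).sum(axis=0) / A.sum()
    mag = float(np.hypot(*q))
    ang = 0.5 * np.arctan2(q[1], q[0]) % np.pi
    return ang, mag


def analyze_run(result: SimulationResult) -> dict:
    """Kinematic summary of a simulation: shape series, nematic readouts,
    shear decomposition, and channel shares of the total."""
    cfg = result.config
    alpha_ref = 0.0 if cfg.stretching else None
    series = shape_series_from_snapshots(result.snapshots, alpha_ref)
    theta_n, mag_n = mesh_mean_nematic(result.snapshots[0][1], result.snapshots[0][2])
    final_fit = colony_moment_ellipse(result.snapshots[-1][1], result.snapshots[-1][2])
    summary = NematicSummary(
        theta_nematic=theta_n,
        magnitude=mag_n,
        theta_colony=final_fit.theta,
    )
    shear = decompose_shear(result.tracked)
    axis = series.alpha_ref
    shares = {
        ch: shear.cumulative_channel(ch, axis)
        for ch in ("total", "elongation", "t1", "division", "extrusion", "correlation")
    }
    return {
        "shape_series": series,
        "nematic_summary": summary,
        "shear": shear,
        "channel_xx_along_ref": shares,
        "delta_theta": fold_nematic_difference(theta_n, final_fit.theta),
        "n_t1_events": len(result.events),
    }


def report_text(analysis: dict) -> str:
    """One-page plain-text report of an analysis dict."""
    s = analysis["nematic_summary"]
    lines = [
        "colony kinematics report",
        "========================",
        f"theta_nematic (t0):   {np.degrees(s.theta_nematic):8.2f} deg",
        f"theta_colony (final): {np.degrees(s.theta_colony):8.2f} deg",
        f"delta_theta:          {np.degrees(analysis['delta_theta']):8.2f} deg",
        f"mean nematic magnitude: {s.magnitude:.4f}",
        f"T1 events: {analysis['n_t1_events']}",
        "",
        "cumulative pure shear along the reference axis (xx):",
    ]
    for ch, val in analysis["channel_xx_along_ref"].items():
        lines.append(f"  {ch:12s} {val:+.4f}")
    return "\n".join(lines)
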