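"""Time integration of the rod system and the deployment protocol.

The rod ODE (lumped masses, diagonal damping, zero rotational inertia) is
integrated with the symplectic (semi-implicit) Euler scheme: velocities
are updated first from the elastic + external forces, positions advance
with the new velocities, and the frame angles follow first-order damped
dynamics ``phi_dot = -grad_Phi E / eta_Phi``.

A deployment run pushes the coil out of the micro-catheter at constant
speed: nodes still inside the catheter are fully kinematic (position
prescribed on the spline, velocity along the local tangent), nodes that
passed the tip evolve freely and are recorded with their release step.
The insertion phase uses the neck-cut dome as the wall; afterwards the
full vessel geometry is enabled for a final settling fraction of steps.
Several coils are inserted sequentially as one chain whose virtual
connecting edges carry no elasticity and no contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from aneucoil.contact import (
    FrictionParams,
    Octree,
    WallSurface,
    assemble_external_forces,
    candidate_pairs_coil,
)
from aneucoil.geometry import AneurysmDomain, CatheterSpline
from aneucoil.rod import (
    CoilSpec,
    NaturalShape,
    RodState,
    grad_energy,
    make_rod_state,
    propagate_bishop,
    rodrigues_rotation,
    total_energy,
)

__all__ = [
    "SimulationConfig",
    "StretchStats",
    "DeploymentResult",
    "step",
    "apply_insertion_bc",
    "run_deployment",
    "compute_stretch_stats",
    "auto_time_step",
    "default_damping",
    "default_friction_params",
    "coil_length_for_packing",
    "simulate_free_rod",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Run configuration (units: mm, s, kg; forces mN).

    ``dt=None`` selects the largest power-of-two fraction of a second
    below the axial CFL-type bound ``0.5 sqrt(m l_bar / alpha_abs)`` (also
    capped by the bending and wall-contact stiffness bounds).  Damping
    defaults are derived from the coil constants: ``eta_X`` near-critical
    for segment-scale bending, ``eta_Phi`` a small multiple of the
    twist-stability limit so the rotational DOFs relax quasistatically.
    """

    dt: float | None = None
    n_steps: int | None = None
    v_push: float = 250.0
    post_swap_fraction: float = 0.10
    settle_fraction: float = 0.05
    gravity: np.ndarray | None = None
    seed: int = 0
    friction: FrictionParams | None = None
    eta_X: float | None = None
    eta_Phi: float | None = None
    target_packing_density: float | None = None
    feed_force_max: float = 6.0
    literal_wall_projection: bool = False
    record_every: int = 0
    diag_every: int = 200

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.post_swap_fraction < 0:
            raise ValueError("post_swap_fraction must be nonnegative")


def auto_time_step(spec: CoilSpec, l_rest: float, k_contact: float | None = None) -> float:
    """Largest power-of-two fraction of a second below the stability bound.

    The binding constraint is the stiffest explicit mode: the axial
    penalty (``0.5 sqrt(m l / alpha_abs)``), segment-scale bending and,
    if given, the wall contact spring.
    """
    m = spec.node_mass(l_rest)
    bounds = [0.5 * np.sqrt(m * l_rest / spec.axial_penalty)]
    k_bend = 4.0 * spec.bend_stiffness / l_rest**3
    bounds.append(0.5 * np.sqrt(m / k_bend))
    if k_contact is not None and k_contact > 0:
        bounds.append(0.5 * np.sqrt(m / k_contact))
    bound = min(bounds)
    return 2.0 ** np.floor(np.log2(bound))


def default_damping(spec: CoilSpec, l_rest: float, dt: float) -> tuple[float, float]:
    """(eta_X, eta_Phi): near-critical translational damping for
    segment-scale bending; rotational damping a safe multiple of the
    explicit twist stability limit (small enough to keep grad_Phi E ~ 0)."""
    m = spec.node_mass(l_rest)
    k_bend = spec.bend_stiffness / l_rest**3
    eta_x = 2.0 * np.sqrt(m * k_bend)
    eta_phi = 20.0 * dt * spec.twist_stiffness / l_rest
    return eta_x, eta_phi


def default_friction_params(spec: CoilSpec, l_rest: float) -> FrictionParams:
    """Contact constants scaled from the bending stiffness.

    Springs are a multiple of ``b / l_bar^3`` so penetrations stay a
    small fraction of the coil diameter under typical elastic loads; the
    friction coefficients are deliberately high (rigid-wall model).
    """
    k_scale = spec.bend_stiffness / l_rest**3
    m = spec.node_mass(l_rest)
    k_w = 5.0 * k_scale
    return FrictionParams(
        k_sc=5.0 * k_scale / spec.D2,
        gamma_sc=0.3 * np.sqrt(m * k_w) / spec.D2**2,
        k_w=k_w,
        gamma_w=0.3 * np.sqrt(m * k_w),
        mu_slip_cc=0.4,
        mu_slip_cw=0.4,
        mu_stick_cw=0.6,
        v_eps=1.0e-3,
    )


def coil_length_for_packing(domain: AneurysmDomain, spec: CoilSpec, packing_density: float) -> float:
    """Coil arc length whose swept volume ``pi (D2/2)^2 L`` reaches the
    requested packing density of the dome volume."""
    return packing_density * domain.V_A / (np.pi * (spec.D2 / 2.0) ** 2)


# ---------------------------------------------------------------------------
# single integration step
# ---------------------------------------------------------------------------


def _advance(
    state: RodState,
    grad_X: np.ndarray,
    grad_Phi: np.ndarray,
    f_ext: np.ndarray,
    mass: np.ndarray,
    eta_x: float,
    eta_phi: float,
    dt: float,
    free_mask: np.ndarray | None = None,
) -> None:
    """In-place symplectic Euler update (velocities first, then positions;
    frame angles by damped first-order dynamics); Bishop frames are
    re-propagated afterwards by the caller."""
    force = -grad_X + f_ext - eta_x * state.velocities
    if not np.all(np.isfinite(force)):
        raise FloatingPointError("non-finite force encountered")
    acc = force / mass[:, None]
    if free_mask is None:
        state.velocities += dt * acc
        state.vertices += dt * state.velocities
    else:
        state.velocities[free_mask] += dt * acc[free_mask]
        state.vertices[free_mask] += dt * state.velocities[free_mask]
    state.edge_angles -= dt * grad_Phi / eta_phi


def step(
    state: RodState,
    natural: NaturalShape,
    spec: CoilSpec,
    f_ext: np.ndarray,
    config: SimulationConfig,
) -> RodState:
    """One symplectic Euler step of a free rod (no insertion, no contact).

    ``f_ext`` is the per-node external force for the current positions
    (explicit contact forces, gravity, ...).  Returns a new state with
    re-propagated Bishop frames; raises ``FloatingPointError`` on
    non-finite forces (instability).
    """
    l_rest = float(np.mean(natural.rest_edge_lengths))
    dt = config.dt if config.dt is not None else auto_time_step(spec, l_rest)
    eta_x, eta_phi = default_damping(spec, l_rest, dt)
    if config.eta_X is not None:
        eta_x = config.eta_X
    if config.eta_Phi is not None:
        eta_phi = config.eta_Phi
    mass = np.full(state.n_vertices, spec.node_mass(l_rest))

    out = state.copy()
    gX, gP = grad_energy(out, natural, spec)
    t0_old = out.tangents[0]
    try:
        _advance(out, gX, gP, np.asarray(f_ext, dtype=float), mass, eta_x, eta_phi, dt)
    except FloatingPointError as err:
        raise FloatingPointError(f"{err} (single step)") from err
    u0 = rodrigues_rotation(t0_old, out.tangents[0]) @ out.bishop_U[0]
    return propagate_bishop(out, U0=u0)


# ---------------------------------------------------------------------------
# insertion boundary condition
# ---------------------------------------------------------------------------


def apply_insertion_bc(
    state: RodState,
    catheter: CatheterSpline,
    arc_positions: np.ndarray,
    v_push: float,
    step_index: int,
) -> np.ndarray:
    """Kinematics for nodes still inside the micro-catheter.

    ``arc_positions`` are the current arc coordinates of all nodes along
    the (extended) catheter centerline; nodes with arc below the tip are
    prescribed ``x = spline(arc)`` and ``v = v_push * tangent(arc)``.
    Nodes crossing the tip this step get their ``release_step`` recorded.
    Returns the boolean mask of released (free) nodes.
    """
    tip = catheter.length
    inside = arc_positions < tip
    newly_released = inside ^ (state.release_step >= 0)
    # nodes that were inside and are now past the tip
    crossed = (~inside) & (state.release_step < 0)
    state.release_step[crossed] = step_index
    if np.any(inside):
        idx = np.flatnonzero(inside)
        state.vertices[idx] = catheter.point_at(arc_positions[idx])
        state.velocities[idx] = v_push * catheter.tangent_at(arc_positions[idx])
    return ~inside


# ---------------------------------------------------------------------------
# stretch statistics
# ---------------------------------------------------------------------------


@dataclass
class StretchStats:
    """Inextensibility diagnostics (all relative, reported in %).

    ``mean_stretch`` averages the per-edge time-averaged relative stretch
    over edges; ``mean_stretch_std`` averages the per-edge time standard
    deviation; ``total_extension`` compares the final total length with
    the nominal coil length.
    """

    per_edge_mean: np.ndarray
    per_edge_var: np.ndarray
    mean_stretch: float
    mean_stretch_std: float
    total_extension: float

    @property
    def mean_stretch_percent(self) -> float:
        return 100.0 * self.mean_stretch

    @property
    def mean_stretch_std_percent(self) -> float:
        return 100.0 * self.mean_stretch_std

    @property
    def total_extension_percent(self) -> float:
        return 100.0 * self.total_extension


def compute_stretch_stats(
    edge_lengths: np.ndarray,
    rest_lengths: np.ndarray,
    release_steps: np.ndarray,
    nominal_length: float | None = None,
) -> StretchStats:
    """Stretch statistics from a recorded trajectory of edge lengths.

    ``edge_lengths`` is (T, n_edges); averaging for edge ``i`` starts at
    its release step (edges never released are excluded with a warning).
    The per-edge time variance is the population variance around the
    per-edge time mean; the aggregate standard deviation averages the
    per-edge standard deviations.  ``total_extension`` uses the final
    sample against the nominal length (default: sum of rest lengths).
    """
    import warnings

    edge_lengths = np.asarray(edge_lengths, dtype=float)
    T, n_e = edge_lengths.shape
    rel = np.abs(edge_lengths / rest_lengths[None, :] - 1.0)
    mean = np.full(n_e, np.nan)
    var = np.full(n_e, np.nan)
    for i in range(n_e):
        n0 = release_steps[i]
        if n0 < 0 or n0 >= T:
            continue
        window = rel[n0:, i]
        mean[i] = window.mean()
        var[i] = window.var()
    ok = np.isfinite(mean)
    if not np.all(ok):
        warnings.warn("edges never released were excluded from stretch statistics")
    if nominal_length is None:
        nominal_length = float(rest_lengths[ok].sum())
    final_total = float(edge_lengths[-1, ok].sum())
    return StretchStats(
        per_edge_mean=mean,
        per_edge_var=var,
        mean_stretch=float(mean[ok].mean()) if ok.any() else 0.0,
        mean_stretch_std=float(np.sqrt(var[ok]).mean()) if ok.any() else 0.0,
        total_extension=abs(nominal_length - final_total) / nominal_length,
    )


class _StretchAccumulator:
    """Online version of the stretch averages (no trajectory
    storage): per-edge running sums from each edge's release step on."""

    def __init__(self, rest_lengths: np.ndarray):
        self.rest = rest_lengths
        n = len(rest_lengths)
        self.s1 = np.zeros(n)
        self.s2 = np.zeros(n)
        self.cnt = np.zeros(n, dtype=np.int64)
        self.last_lengths = rest_lengths.copy()

    def update(self, lengths: np.ndarray, edge_released: np.ndarray) -> None:
        rel = np.abs(lengths / self.rest - 1.0)
        self.s1[edge_released] += rel[edge_released]
        self.s2[edge_released] += rel[edge_released] ** 2
        self.cnt[edge_released] += 1
        self.last_lengths = lengths

    def finalize(self, nominal_length: float | None = None) -> StretchStats:
        ok = self.cnt > 0
        mean = np.full(len(self.rest), np.nan)
        var = np.full(len(self.rest), np.nan)
        mean[ok] = self.s1[ok] / self.cnt[ok]
        var[ok] = np.maximum(self.s2[ok] / self.cnt[ok] - mean[ok] ** 2, 0.0)
        if nominal_length is None:
            nominal_length = float(self.rest[ok].sum())
        final_total = float(self.last_lengths[ok].sum())
        return StretchStats(
            per_edge_mean=mean,
            per_edge_var=var,
            mean_stretch=float(mean[ok].mean()) if ok.any() else 0.0,
            mean_stretch_std=float(np.sqrt(var[ok]).mean()) if ok.any() else 0.0,
            total_extension=abs(nominal_length - final_total) / nominal_length
            if ok.any()
            else 0.0,
        )


# ---------------------------------------------------------------------------
# deployment
# ---------------------------------------------------------------------------


@dataclass
class DeploymentResult:
    """Outcome of a (multi-)coil deployment."""

    states: list[RodState]
    naturals: list[NaturalShape]
    specs: list[CoilSpec]
    stretch: StretchStats
    inserted_length: float
    n_steps: int
    dt: float
    diagnostics: dict = field(default_factory=dict)
    trajectory: list = field(default_factory=list)

    @property
    def centerline(self) -> np.ndarray:
        """Concatenated deployed centerline(s) of released nodes."""
        parts = [s.vertices[s.release_step >= 0] for s in self.states]
        return np.concatenate([p for p in parts if len(p)], axis=0)

    def centerlines(self) -> list[np.ndarray]:
        return [s.vertices[s.release_step >= 0] for s in self.states]


class _GlobalView:
    """Concatenated polyline view over several coils for contact queries."""

    def __init__(self, vertices: np.ndarray, velocities: np.ndarray):
        self.vertices = vertices
        self.velocities = velocities

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vertices[1:] - self.vertices[:-1], axis=1)


def run_deployment(
    domain: AneurysmDomain,
    coils: list[tuple[CoilSpec, NaturalShape]],
    catheter: CatheterSpline,
    config: SimulationConfig,
) -> DeploymentResult:
    """Deploy one or more coils sequentially into the aneurysm.

    Phase 1 collides against the closed neck-cut dome (plus the catheter
    tube); the final ``post_swap_fraction`` of steps replaces the dome by
    the full vessel mesh.  Initial condition: each coil straight behind
    the catheter inlet with a twist-free Bishop frame; it is fed through
    the catheter at ``v_push`` and nodes become dynamic at the tip.
    """
    if not coils:
        raise ValueError("need at least one coil")
    specs = [c[0] for c in coils]
    naturals = [c[1] for c in coils]
    for sp, nat in zip(specs, naturals):
        if len(nat.natural_vertices) < 2:
            raise ValueError("coil with fewer than 2 nodes")

    # --- chain layout ----------------------------------------------------
    counts = [len(nat.natural_vertices) for nat in naturals]
    offsets = np.concatenate([[0], np.cumsum(counts)])  # node offsets per coil
    n_total = offsets[-1]
    l_ref = float(np.mean(naturals[0].rest_edge_lengths))
    gap = l_ref  # rest length assigned to the virtual inter-coil edges

    # global edge activity: edges inside a coil are real, inter-coil edges
    # virtual (no elasticity, no contact)
    edge_virtual = np.zeros(n_total - 1, dtype=bool)
    for c in range(len(coils) - 1):
        edge_virtual[offsets[c + 1] - 1] = True
    rest_all = np.full(n_total - 1, gap)
    for c, nat in enumerate(naturals):
        rest_all[offsets[c] : offsets[c + 1] - 1] = nat.rest_edge_lengths

    # arc coordinate of each node on the extended catheter line at t=0:
    # coil 0 leads, its tip node (last node of coil 0) starts at the inlet
    arc0 = np.empty(n_total)
    lead = 0.0
    for c, nat in enumerate(naturals):
        nc = counts[c]
        lens = nat.rest_edge_lengths
        # within a coil the last node is the leading (tip) one
        rel = np.concatenate([[0.0], np.cumsum(lens[::-1])])[::-1]
        arc0[offsets[c] : offsets[c + 1]] = lead - rel
        lead = arc0[offsets[c]] - gap
    # inserted nominal length (only what the packing target requires)
    total_nominal = float(rest_all[~edge_virtual].sum())
    if config.target_packing_density is not None:
        l_target = coil_length_for_packing(domain, specs[0], config.target_packing_density)
        l_target = min(l_target, total_nominal)
    else:
        l_target = total_nominal

    # --- numerics --------------------------------------------------------
    spec0 = specs[0]
    friction = config.friction or default_friction_params(spec0, l_ref)
    k_contact = max(friction.k_w, friction.k_sc * spec0.D2)
    dt = config.dt if config.dt is not None else auto_time_step(spec0, l_ref, k_contact)
    eta_x, eta_phi = default_damping(spec0, l_ref, dt)
    if config.eta_X is not None:
        eta_x = config.eta_X
    if config.eta_Phi is not None:
        eta_phi = config.eta_Phi
    masses = np.concatenate(
        [
            np.full(counts[c], specs[c].node_mass(float(np.mean(naturals[c].rest_edge_lengths))))
            for c in range(len(coils))
        ]
    )

    # steps: push l_target plus the catheter length past the tip, then
    # settle, then the geometry-swap fraction
    arc_to_push = l_target + catheter.length
    n_insert = int(np.ceil(arc_to_push / (config.v_push * dt)))
    n_settle = int(np.ceil(config.settle_fraction * n_insert))
    n_post = int(np.ceil(config.post_swap_fraction * (n_insert + n_settle)))

    # --- initial states --------------------------------------------------
    states: list[RodState] = []
    for c in range(len(coils)):
        sl = slice(offsets[c], offsets[c + 1])
        pts = catheter.point_at(arc0[sl])
        st = make_rod_state(pts, reference_director=None)
        st.velocities[:] = config.v_push * catheter.tangent_at(arc0[sl])
        states.append(st)

    walls_phase1 = [
        WallSurface.from_trimesh(domain.dome_mesh),
        WallSurface.from_trimesh(catheter.tube_mesh()),
    ]
    walls_phase2 = [
        WallSurface.from_trimesh(domain.vessel_mesh),
        walls_phase1[1],
    ]

    acc = _StretchAccumulator(rest_all)
    gravity = None
    if config.gravity is not None:
        gravity = np.asarray(config.gravity, dtype=float)

    diag_hist: list[tuple] = []
    max_fric_ratio = 0.0
    max_antisym = 0.0
    max_penetration = 0.0
    trajectory: list[tuple[int, np.ndarray]] = []

    release_global = np.zeros(n_total, dtype=bool)

    # broad-phase cache state
    cache_margin = 0.5 * spec0.D2
    cache_pos: np.ndarray | None = None
    cache_swap = False
    cache_released = -1
    cached_pairs: np.ndarray | None = None
    cached_walls: list | None = None

    # phase machine: INSERT until the packing target (or whole length) is
    # released, then SETTLE, then swap in the full vessel for the final
    # fraction.  The conveyor is force limited: it pauses whenever the
    # axial force in the feed edge (last in-catheter node to first
    # released node) exceeds the push-force bound, emulating the
    # interventionist's bounded push; a stalled insertion therefore takes
    # extra steps, bounded by the hard cap below.  The compression is
    # additionally capped so edges cannot collapse at very soft axial
    # penalties.
    comp_threshold = min(config.feed_force_max / spec0.axial_penalty, 0.3)
    push = 0.0
    phase = "insert"
    phase_left = 0
    inserting = True
    max_steps = 3 * n_insert + n_settle + n_post
    if config.n_steps is not None:
        max_steps = config.n_steps
    n = 0
    swap_done = False
    n_steps_insert_used = 0

    while n < max_steps:
        if phase == "insert":
            feed_ok = True
            for c, st in enumerate(states):
                rel = st.release_step >= 0
                if rel.any() and not rel.all():
                    k = int(np.argmax(rel))
                    if k >= 1:
                        ln = np.linalg.norm(st.vertices[k] - st.vertices[k - 1])
                        if ln / naturals[c].rest_edge_lengths[k - 1] - 1.0 < -comp_threshold:
                            feed_ok = False
                    break
            if feed_ok:
                push += config.v_push * dt
            inserting = feed_ok
        arcs = arc0 + push

        free_masks = []
        for c, st in enumerate(states):
            sl = slice(offsets[c], offsets[c + 1])
            free = apply_insertion_bc(
                st, catheter, arcs[sl], config.v_push if (phase == "insert" and inserting) else 0.0, n
            )
            free_masks.append(free)
            release_global[sl] = free

        # elastic forces per coil
        gX_all = np.zeros((n_total, 3))
        gP_list = []
        for c, st in enumerate(states):
            gX, gP = grad_energy(st, naturals[c], specs[c])
            gX_all[offsets[c] : offsets[c + 1]] = gX
            gP_list.append(gP)

        f_int = -gX_all
        if gravity is not None:
            f_int = f_int + masses[:, None] * gravity

        # contact on the concatenated chain.  Broad-phase candidates are
        # cached with a displacement-bounded margin: as long as no node
        # moved more than half the margin since the octrees were built,
        # the cached sets remain supersets of the true candidates, and
        # the exact per-step narrow phase reproduces a full rebuild.
        verts_all = np.concatenate([st.vertices for st in states])
        vels_all = np.concatenate([st.velocities for st in states])
        view = _GlobalView(verts_all, vels_all)
        walls = walls_phase2 if swap_done else walls_phase1
        n_released = int(release_global.sum())
        refresh = (
            cache_pos is None
            or swap_done != cache_swap
            or n_released != cache_released
            or float(np.max(np.sum((verts_all - cache_pos) ** 2, axis=1)))
            > (0.5 * cache_margin) ** 2
        )
        if refresh:
            centers = 0.5 * (verts_all[:-1] + verts_all[1:])
            octree = Octree(centers)
            cached_pairs = candidate_pairs_coil(
                view, octree, l_ref, spec0.D2,
                active_edges=(~edge_virtual) & release_global[:-1] & release_global[1:],
                extra_radius=cache_margin,
            )
            cached_walls = []
            for wall in walls:
                r_q = spec0.D2 / 2.0 + float(wall.r_st.max()) + cache_margin
                qi, ti = wall.octree.query_batch(verts_all, r_q)
                keep = (
                    np.linalg.norm(verts_all[qi] - wall.centers[ti], axis=1)
                    <= spec0.D2 / 2.0 + wall.r_st[ti] + cache_margin
                )
                cached_walls.append((qi[keep], ti[keep]))
            cache_pos = verts_all.copy()
            cache_swap = swap_done
            cache_released = n_released
        f_ext, diag = assemble_external_forces(
            view,
            walls,
            friction,
            spec0.D2,
            f_int,
            rest_length=l_ref,
            active_edges=~edge_virtual,
            active_nodes=release_global,
            literal_projection=config.literal_wall_projection,
            dv_cap=0.5 * float(masses.min()) / dt,
            coil_pairs=cached_pairs,
            wall_candidates=cached_walls,
        )
        max_fric_ratio = max(max_fric_ratio, diag.max_friction_ratio)
        max_antisym = max(max_antisym, diag.antisymmetry_residual)
        max_penetration = max(max_penetration, diag.max_penetration)

        # integrate
        for c, st in enumerate(states):
            sl = slice(offsets[c], offsets[c + 1])
            if gravity is not None:
                fx = f_ext[sl] + masses[sl][:, None] * gravity
            else:
                fx = f_ext[sl]
            t0_old = st.tangents[0]
            try:
                _advance(
                    st,
                    gX_all[sl],
                    gP_list[c],
                    fx,
                    masses[sl],
                    eta_x,
                    eta_phi,
                    dt,
                    free_mask=free_masks[c],
                )
            except FloatingPointError as err:
                raise FloatingPointError(f"instability at step {n}: {err}") from err
            u0 = rodrigues_rotation(t0_old, st.tangents[0]) @ st.bishop_U[0]
            st.bishop_U[0] = u0
            states[c] = propagate_bishop(st, U0=u0)

        # stretch accounting on fully released real edges
        lengths_all = np.linalg.norm(
            np.concatenate([st.vertices for st in states])[1:]
            - np.concatenate([st.vertices for st in states])[:-1],
            axis=1,
        )
        edge_rel = release_global[:-1] & release_global[1:] & ~edge_virtual
        acc.update(lengths_all, edge_rel)

        # phase transitions
        if phase == "insert":
            released_len = float(rest_all[edge_rel].sum())
            if released_len >= l_target or push >= arc_to_push + 2 * l_ref:
                phase = "settle"
                phase_left = n_settle
                n_steps_insert_used = n + 1
        elif phase == "settle":
            phase_left -= 1
            if phase_left <= 0:
                phase = "post"
                phase_left = n_post
                swap_done = True
        elif phase == "post":
            phase_left -= 1
            if phase_left <= 0:
                n += 1
                break

        if config.record_every and n % config.record_every == 0:
            trajectory.append((n, np.concatenate([st.vertices.copy() for st in states])))
        if config.diag_every and n % config.diag_every == 0:
            energy = sum(
                total_energy(states[c], naturals[c], specs[c]) for c in range(len(coils))
            )
            diag_hist.append(
                (n, float(rest_all[edge_rel].sum()), energy, diag.n_coil_pairs, diag.n_wall, diag.max_penetration)
            )
        n += 1

    edge_rel = release_global[:-1] & release_global[1:] & ~edge_virtual
    stats = acc.finalize(nominal_length=float(rest_all[edge_rel].sum()) or None)
    return DeploymentResult(
        states=states,
        naturals=naturals,
        specs=specs,
        stretch=stats,
        inserted_length=float(rest_all[edge_rel].sum()),
        n_steps=n,
        dt=dt,
        diagnostics={
            "insertion_complete": phase == "post" and phase_left <= 0,
            "n_steps_insert": n_steps_insert_used,
            "max_friction_cap_ratio": max_fric_ratio,
            "max_pair_antisymmetry_residual": max_antisym,
            "max_penetration": max_penetration,
            "history": diag_hist,
            "history_columns": [
                "step",
                "inserted_length_mm",
                "elastic_energy_uJ",
                "coil_pairs",
                "wall_contacts",
                "max_penetration_mm",
            ],
        },
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# free-space integration (validation scenarios)
# ---------------------------------------------------------------------------


def simulate_free_rod(
    state: RodState,
    natural: NaturalShape,
    spec: CoilSpec,
    n_steps: int,
    dt: float | None = None,
    eta_x: float | None = None,
    eta_phi: float | None = None,
    gravity: np.ndarray | None = None,
    clamp_nodes: np.ndarray | None = None,
    energy_every: int = 0,
) -> tuple[RodState, list[float]]:
    """Integrate a rod without walls or insertion (shape recovery,
    gravity sag, cantilever checks).  ``clamp_nodes`` holds the listed
    node indices fixed.  Returns the final state and sampled energies.
    """
    l_rest = float(np.mean(natural.rest_edge_lengths))
    if dt is None:
        dt = auto_time_step(spec, l_rest)
    dx, dphi = default_damping(spec, l_rest, dt)
    eta_x = dx if eta_x is None else eta_x
    eta_phi = dphi if eta_phi is None else eta_phi
    mass = np.full(state.n_vertices, spec.node_mass(l_rest))
    free = np.ones(state.n_vertices, dtype=bool)
    if clamp_nodes is not None:
        free[np.asarray(clamp_nodes, dtype=int)] = False

    st = state.copy()
    energies: list[float] = []
    for n in range(n_steps):
        gX, gP = grad_energy(st, natural, spec)
        f_ext = np.zeros_like(st.vertices)
        if gravity is not None:
            f_ext += mass[:, None] * np.asarray(gravity, dtype=float)
        t0_old = st.tangents[0]
        try:
            _advance(st, gX, gP, f_ext, mass, eta_x, eta_phi, dt, free_mask=free)
        except FloatingPointError as err:
            raise FloatingPointError(f"instability at step {n}: {err}") from err
        u0 = rodrigues_rotation(t0_old, st.tangents[0]) @ st.bishop_U[0]
        st = propagate_bishop(st, U0=u0)
        if energy_every and n % energy_every == 0:
            energies.append(total_energy(st, natural, spec))
    return st, energies
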