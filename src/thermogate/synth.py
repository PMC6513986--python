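"""Synthetic inputs with declared ground truth.

Every generator is a pure function of its parameters and seed, and embeds a
:class:`GeneratorSpec` (``.spec`` attribute on the returned artifact) so the
truth is recoverable by tests: analytic pore structures for the profiler,
C4 helix bundles with a perturbable loop for the refinement sampler, decoy
sets with prescribed burial/energy statistics, heat-ramp current traces,
skew-Gaussian emission spectra, FRET ratio time courses and 1:1 Langmuir
sensorgrams.

Noise is additive Gaussian throughout, with the standard deviation
expressed as a fraction of the signal maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _backbone as bb
from .structures import ChannelStructure, LoopSpec
from .signals import CurrentTrace, EmissionSpectrum, FretTimeCourse, skew_gauss
from .binding import Sensorgram, simulate_sensorgram
from .ensemble import DecoyModel

__all__ = [
    "GeneratorSpec",
    "make_ring_stack",
    "make_hourglass",
    "make_c4_bundle",
    "make_decoy_set",
    "synth_current_trace",
    "synth_spectrum",
    "synth_fret_timecourse",
    "synth_sensorgram",
    "plateau_for_degree",
]


@dataclass
class GeneratorSpec:
    """What a synthetic artifact was generated from: kind, all ground-truth
    parameters, and the seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _structure_from_coords(
    coords: np.ndarray,
    radius: float,
    res_ids: np.ndarray,
    chain_ids: np.ndarray | None = None,
    element: str = "C",
) -> ChannelStructure:
    n = len(coords)
    s = ChannelStructure(
        ids=np.arange(1, n + 1),
        elements=np.full(n, element),
        atom_names=np.full(n, element),
        res_ids=np.asarray(res_ids, dtype=int),
        res_names=np.full(n, "ALA"),
        chain_ids=(np.full(n, "A") if chain_ids is None
                   else np.asarray(chain_ids)),
        coords=coords,
        hetero=np.zeros(n, dtype=bool),
    )
    s.radii = np.full(n, float(radius))
    return s


# ---------------------------------------------------------------------------
# Analytic pore structures
# ---------------------------------------------------------------------------

def make_ring_stack(
    ring_radius: float = 5.0,
    atom_radius: float = 1.7,
    n_rings: int = 10,
    spacing: float = 2.0,
    atoms_per_ring: int = 12,
) -> ChannelStructure:
    """Stacked rings of atoms about +z: an analytic cylinder pore.

    At every ring plane the pore radius is exactly
    ``ring_radius − atom_radius``; between planes it exceeds that by at
    most ``spacing²/(8·ring_radius)`` (angular leakage between ring atoms
    adds a similar correction that shrinks with ``atoms_per_ring``).
    """
    if ring_radius <= atom_radius:
        raise ValueError("ring_radius must exceed atom_radius")
    z0 = -spacing * (n_rings - 1) / 2.0
    coords, res = [], []
    for k in range(n_rings):
        for a in range(atoms_per_ring):
            ang = 2 * np.pi * a / atoms_per_ring
            coords.append([ring_radius * np.cos(ang),
                           ring_radius * np.sin(ang),
                           z0 + k * spacing])
            res.append(k + 1)
    s = _structure_from_coords(np.array(coords), atom_radius, np.array(res))
    s.spec = GeneratorSpec("ring_stack", dict(
        ring_radius=ring_radius, atom_radius=atom_radius, n_rings=n_rings,
        spacing=spacing, atoms_per_ring=atoms_per_ring,
        pore_radius=ring_radius - atom_radius,
        z_min=z0, z_max=-z0,
    ))
    return s


def make_hourglass(
    neck_radius: float = 0.7,
    mouth_radius: float = 5.0,
    half_length: float = 10.0,
    atom_radius: float = 1.7,
    spacing: float = 1.0,
    atoms_per_ring: int = 24,
) -> ChannelStructure:
    """Rings tapering linearly to a neck at z = 0 (analytic hourglass).

    The analytic pore radius is piecewise linear,
    r(z) = neck + (mouth − neck)·|z|/half_length, with its minimum
    ``neck_radius`` at z = 0.
    """
    if neck_radius >= mouth_radius:
        raise ValueError("neck_radius must be smaller than mouth_radius")
    if neck_radius <= 0 or half_length <= 0:
        raise ValueError("invalid hourglass geometry")
    zs = np.arange(-half_length, half_length + spacing / 2, spacing)
    coords, res = [], []
    for k, z in enumerate(zs):
        r_pore = neck_radius + (mouth_radius - neck_radius) \
            * abs(z) / half_length
        ring_r = r_pore + atom_radius
        for a in range(atoms_per_ring):
            ang = 2 * np.pi * a / atoms_per_ring
            coords.append([ring_r * np.cos(ang), ring_r * np.sin(ang), z])
            res.append(k + 1)
    s = _structure_from_coords(np.array(coords), atom_radius, np.array(res))
    s.spec = GeneratorSpec("hourglass", dict(
        neck_radius=neck_radius, mouth_radius=mouth_radius,
        half_length=half_length, atom_radius=atom_radius, spacing=spacing,
        atoms_per_ring=atoms_per_ring,
    ))
    return s


# ---------------------------------------------------------------------------
# C4 helix bundle with a perturbable loop
# ---------------------------------------------------------------------------

def make_c4_bundle(
    n_helix: int = 10,
    loop_len: int = 8,
    bundle_radius: float = 6.0,
    element_radius: float = 1.7,
) -> tuple[ChannelStructure, LoopSpec]:
    """Four-fold symmetric helix bundle with a solvent-exposed loop.

    Each chain is an α-helix interrupted by an extended loop segment whose
    middle residue is the marker site; the chain is oriented so the loop
    bulges radially outward, leaving the marker maximally exposed, so that
    random loop perturbations can bury it against the bundle core.
    Returns the aligned, radii-assigned structure and the
    :class:`LoopSpec` naming the loop segment and marker for refinement.
    """
    n_res = 2 * n_helix + loop_len
    phi_psi = [(-57.0, -47.0)] * n_helix \
        + [(-100.0, 120.0)] * loop_len \
        + [(-57.0, -47.0)] * n_helix
    backbone = bb.helix_backbone(n_res, phi_psi)

    # Full atom set: N, CA, C, O, CB per residue.
    names, coords, res_ids = [], [], []
    for j in range(n_res):
        n_, ca, c = backbone[3 * j], backbone[3 * j + 1], backbone[3 * j + 2]
        n_next = backbone[3 * j + 3] if j + 1 < n_res else None
        for nm, pos in (("N", n_), ("CA", ca), ("C", c)):
            names.append(nm)
            coords.append(pos)
            res_ids.append(j + 1)
        if n_next is not None:
            names.append("O")
            coords.append(bb.place_o(ca, c, n_next))
            res_ids.append(j + 1)
        names.append("CB")
        coords.append(bb.place_cb(n_, ca, c))
        res_ids.append(j + 1)
    coords = np.array(coords)

    # Orient the chain's long axis along z and offset it from the origin.
    cas = backbone[1::3]
    center = cas.mean(axis=0)
    axis = np.linalg.svd(cas - center, full_matrices=False)[2][0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s_ = np.linalg.norm(v)
    if s_ > 1e-12:
        c_ = float(axis @ z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c_) / s_**2)
    else:
        rot = np.eye(3)
    coords = (coords - center) @ rot.T
    # Spin the chain about its own axis so the loop's lateral bulge points
    # along +x; the chain is then offset to +x, putting the bulge radially
    # outward (maximally exposed marker).
    loop_res = range(n_helix, n_helix + loop_len)
    # atoms are in build order, 5 per residue (N, CA, C, O, CB) except the
    # last residue which lacks O
    ca_idx = []
    k = 0
    for j in range(n_res):
        ca_idx.append(k + 1)
        k += 5 if j + 1 < n_res else 4
    loop_cas = coords[[ca_idx[j] for j in loop_res]]
    bulge = loop_cas.mean(axis=0)
    bulge[2] = 0.0
    if np.linalg.norm(bulge) > 1e-9:
        ang = -np.arctan2(bulge[1], bulge[0])
        spin = np.array([[np.cos(ang), -np.sin(ang), 0],
                         [np.sin(ang), np.cos(ang), 0],
                         [0, 0, 1]])
        coords = coords @ spin.T
    coords[:, 0] += bundle_radius

    # Four chains by rotation about +z.
    all_coords, all_names, all_res, all_chain = [], [], [], []
    for k, chain in enumerate("ABCD"):
        ang = np.pi * k / 2
        rotz = np.array([[np.cos(ang), -np.sin(ang), 0],
                         [np.sin(ang), np.cos(ang), 0],
                         [0, 0, 1]])
        all_coords.append(coords @ rotz.T)
        all_names.extend(names)
        all_res.extend(res_ids)
        all_chain.extend([chain] * len(names))
    all_coords = np.vstack(all_coords)
    n = len(all_coords)
    struct = ChannelStructure(
        ids=np.arange(1, n + 1),
        elements=np.where(np.char.startswith(np.array(all_names), "N"), "N",
                          np.where(np.char.startswith(np.array(all_names),
                                                      "O"), "O", "C")),
        atom_names=np.array(all_names),
        res_ids=np.array(all_res),
        res_names=np.full(n, "ALA"),
        chain_ids=np.array(all_chain),
        coords=all_coords - all_coords.mean(axis=0),
        hetero=np.zeros(n, dtype=bool),
    )
    struct.radii = np.full(n, float(element_radius))
    loop_start = n_helix + 1
    loop_end = n_helix + loop_len
    marker = n_helix + (loop_len + 1) // 2
    loops = LoopSpec(segments=[("A", loop_start, loop_end)],
                     marker_site=marker)
    struct.spec = GeneratorSpec("c4_bundle", dict(
        n_helix=n_helix, loop_len=loop_len, bundle_radius=bundle_radius,
        loop_start=loop_start, loop_end=loop_end, marker_site=marker,
    ))
    return struct, loops


# ---------------------------------------------------------------------------
# Decoy sets with prescribed statistics
# ---------------------------------------------------------------------------

def make_decoy_set(
    n: int,
    delta_sasa_distribution: tuple[float, float] = (20.0, 5.0),
    energy_distribution: tuple[float, float] = (100.0, 10.0),
    correlation: float = 0.0,
    seed: int | None = None,
    base_structure: ChannelStructure | None = None,
) -> list[DecoyModel]:
    """Lightweight decoys with (burial, energy) drawn from a bivariate
    normal with the given means, standard deviations and correlation.

    All decoys share ``base_structure`` (a tiny placeholder by default);
    this exercises the filter/selection logic at scale without structural
    sampling.  The drawn values are the ground truth, embedded in the
    returned models' shared ``spec``.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    mu = np.array([delta_sasa_distribution[0], energy_distribution[0]])
    sd = np.array([delta_sasa_distribution[1], energy_distribution[1]])
    z = rng.standard_normal((n, 2))
    z2 = correlation * z[:, 0] + np.sqrt(max(0.0, 1 - correlation**2)) \
        * z[:, 1]
    burial = mu[0] + sd[0] * z[:, 0]
    energy = mu[1] + sd[1] * z2
    if base_structure is None:
        base_structure = _structure_from_coords(
            np.zeros((1, 3)), 1.7, np.array([1]))
    spec = GeneratorSpec("decoy_set", dict(
        n=n, delta_sasa_distribution=delta_sasa_distribution,
        energy_distribution=energy_distribution, correlation=correlation,
        burial=burial, energy=energy,
    ), seed)
    decoys = [
        DecoyModel(base_structure, float(energy[i]), float(burial[i]),
                   round_index=1, decoy_id=i, seed=seed)
        for i in range(n)
    ]
    for d in decoys:
        d.spec = spec
    return decoys


# ---------------------------------------------------------------------------
# Current traces
# ---------------------------------------------------------------------------

def _leak(T, leak_25: float, q10_leak: float):
    return leak_25 * q10_leak ** ((np.asarray(T) - 25.0) / 10.0)


def plateau_for_degree(degree_percent: float) -> float:
    """Plateau fraction encoding a desired degree of desensitization.

    Inverts degree = 100·(1 − plateau) for a leak-subtracted constant-T
    trace (generate with ``leak_25=0``, the analogue of a leak-corrected
    recording); a plateau of 0.007 encodes a 99.3% degree.
    """
    if not 0.0 <= degree_percent <= 100.0:
        raise ValueError("degree must be within [0, 100] percent")
    return 1.0 - degree_percent / 100.0


def synth_current_trace(
    threshold_T: float = 35.0,
    tau_activation: float = 0.2,
    tau_desensitization: float = 17.3,
    plateau_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    start_T: float = 25.0,
    hold_T: float = 48.0,
    ramp_rate: float = 1.0,
    hold_duration: float = 300.0,
    dt: float = 0.1,
    imax: float = 2000.0,
    leak_25: float = 100.0,
    q10_leak: float = 1.3,
) -> CurrentTrace:
    """Heat-evoked current over a linear ramp followed by a constant hold.

    The temperature ramps from ``start_T`` to ``hold_T`` at ``ramp_rate``
    °C/s and then holds; ``start_T == hold_T`` gives a pure constant-T
    (temperature-step) trace, and ``leak_25 = 0`` emulates a
    leak-subtracted recording.  The current is leak plus an activated
    component:
    in Arrhenius coordinates log10 I is exactly piecewise linear with the
    breakpoint at ``threshold_T`` (leak Q10 below; a steep activated limb
    above, scaled so the activated amplitude reaches ``imax`` at the hold
    temperature).  Activation relaxes toward its equilibrium with
    ``tau_activation`` (0 = instantaneous); during the hold the activated
    component desensitizes mono-exponentially with ``tau_desensitization``
    toward ``plateau_fraction``·imax.  Noise is Gaussian with sd
    ``noise_sd`` × max |I|.
    """
    if tau_desensitization <= 0 or tau_activation < 0:
        raise ValueError("time constants must be positive")
    if not 0.0 <= plateau_fraction <= 1.0:
        raise ValueError("plateau_fraction must be within [0, 1]")
    # A protocol that never crosses the threshold yields a leak-only trace.
    rng = np.random.default_rng(seed)
    t_ramp = (hold_T - start_T) / ramp_rate
    t = np.arange(0.0, t_ramp + hold_duration + dt / 2, dt)
    T = np.minimum(start_T + ramp_rate * t, hold_T)

    # Piecewise-linear Arrhenius design: below the threshold the current
    # is the leak; above it the current follows a steep activated limb
    # that takes over continuously at the threshold and reaches imax at
    # hold_T, so log10 I against 1/T is exactly continuous piecewise
    # linear with its break at threshold_T.  Without a leak
    # (leak-subtracted traces) the activated amplitude is simply imax.
    if hold_T <= threshold_T:
        i_eq = _leak(T, leak_25, q10_leak) * np.ones_like(T)
    elif leak_25 > 0:
        x = 1.0 / (T + 273.15)
        x_thr = 1.0 / (threshold_T + 273.15)
        x_hold = 1.0 / (hold_T + 273.15)
        leak_thr = float(_leak(threshold_T, leak_25, q10_leak))
        slope_act = (np.log10(imax) - np.log10(leak_thr)) / (x_hold - x_thr)
        i_eq = np.where(
            T >= threshold_T,
            10.0 ** (np.log10(leak_thr) + slope_act * (x - x_thr)),
            _leak(T, leak_25, q10_leak),
        )
    else:
        i_eq = np.where(T >= threshold_T, float(imax), 0.0)
    # First-order relaxation of the heat-evoked (above-leak) component
    # toward its equilibrium; the leak itself follows temperature
    # instantly.
    base = _leak(T, leak_25, q10_leak) * np.ones_like(T)
    excess_eq = i_eq - base
    if tau_activation > 0:
        excess = np.empty_like(excess_eq)
        excess[0] = excess_eq[0]
        decay = np.exp(-dt / tau_activation)
        for i in range(1, len(t)):
            excess[i] = excess_eq[i] + (excess[i - 1] - excess_eq[i]) * decay
        act = base + excess
    else:
        act = i_eq
    # Desensitization engages at the hold (constant-temperature) phase
    # and scales the heat-evoked (above-leak) component.
    d = np.ones_like(t)
    hold = t >= t_ramp
    d[hold] = plateau_fraction + (1.0 - plateau_fraction) * np.exp(
        -(t[hold] - t_ramp) / tau_desensitization)
    leak_hold = float(_leak(hold_T, leak_25, q10_leak))
    current = np.where(hold, leak_hold + (act - leak_hold) * d, act)
    if noise_sd > 0:
        current = current + noise_sd * float(np.max(np.abs(current))) \
            * rng.standard_normal(len(t))
    trace = CurrentTrace(t, current, T)
    trace.spec = GeneratorSpec("current_trace", dict(
        threshold_T=threshold_T, tau_activation=tau_activation,
        tau_desensitization=tau_desensitization,
        plateau_fraction=plateau_fraction, noise_sd=noise_sd,
        start_T=start_T, hold_T=hold_T, ramp_rate=ramp_rate,
        hold_duration=hold_duration, dt=dt, imax=imax, leak_25=leak_25,
        q10_leak=q10_leak, t_ramp=t_ramp,
        true_degree=100.0 * (1.0 - plateau_fraction) * imax
        / (imax + float(_leak(hold_T, leak_25, q10_leak))),
    ), seed)
    return trace


# ---------------------------------------------------------------------------
# Spectra and FRET
# ---------------------------------------------------------------------------

def synth_spectrum(
    peaks=((1.0, 480.0, 30.0, 2.0),),
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    wl_range: tuple[float, float] = (400.0, 650.0),
    d_wl: float = 1.0,
) -> EmissionSpectrum:
    """Skew-Gaussian mixture emission spectrum.

    ``peaks`` is a sequence of (amplitude, location ξ, scale ω, shape α)
    tuples.  The true λmax of each peak (argmax of its noiseless curve on
    a 0.01 nm grid) is embedded in the spec.
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(wl_range[0], wl_range[1] + d_wl / 2, d_wl)
    y = np.full_like(wl, float(baseline))
    lambda_maxes = []
    fine = np.arange(wl_range[0], wl_range[1], 0.01)
    for amp, loc, scale, shape in peaks:
        y = y + skew_gauss(wl, amp, loc, scale, shape)
        curve = skew_gauss(fine, amp, loc, scale, shape)
        lambda_maxes.append(float(fine[int(np.argmax(curve))]))
    if noise_sd > 0:
        y = y + noise_sd * float(np.max(y)) * rng.standard_normal(len(wl))
    spectrum = EmissionSpectrum(wl, y)
    spectrum.spec = GeneratorSpec("spectrum", dict(
        peaks=tuple(tuple(p) for p in peaks), baseline=baseline,
        noise_sd=noise_sd, lambda_max=lambda_maxes,
    ), seed)
    return spectrum


def synth_fret_timecourse(
    tau: float = 14.9,
    start_ratio: float = 1.0,
    end_ratio: float = 0.6,
    noise_sd: float = 0.0,
    seed: int | None = None,
    start_T: float = 25.0,
    hold_T: float = 45.0,
    ramp_rate: float = 1.0,
    hold_duration: float = 60.0,
    dt: float = 0.1,
    control_slope: float = 0.01,
) -> tuple[FretTimeCourse, FretTimeCourse]:
    """Raw FRET ratio trace plus the matching control-construct curve.

    The underlying (true) acceptor/donor ratio is constant at
    ``start_ratio`` during the heating ramp and relaxes mono-exponentially
    to ``end_ratio`` with time constant ``tau`` during the constant-T hold
    — the ratio analogue of a desensitization time course.  The *raw*
    trace is the truth multiplied by a temperature-dependent control
    factor 1 + ``control_slope``·(T − start_T), emulating the intrinsic
    temperature sensitivity of the fluorophores; the returned control
    trace samples that factor over a temperature sweep so
    ``correct_fret_ratio`` can divide it out.
    """
    rng = np.random.default_rng(seed)
    t_ramp = (hold_T - start_T) / ramp_rate
    t = np.arange(0.0, t_ramp + hold_duration + dt / 2, dt)
    T = np.minimum(start_T + ramp_rate * t, hold_T)
    truth = np.full_like(t, start_ratio)
    hold = t >= t_ramp
    truth[hold] = end_ratio + (start_ratio - end_ratio) * np.exp(
        -(t[hold] - t_ramp) / tau)
    control_factor = 1.0 + control_slope * (T - start_T)
    raw = truth * control_factor
    if noise_sd > 0:
        raw = raw + noise_sd * float(np.max(raw)) \
            * rng.standard_normal(len(t))
        raw = np.maximum(raw, 1e-6)
    spec = GeneratorSpec("fret", dict(
        tau=tau, start_ratio=start_ratio, end_ratio=end_ratio,
        noise_sd=noise_sd, start_T=start_T, hold_T=hold_T,
        ramp_rate=ramp_rate, hold_duration=hold_duration, dt=t_ramp,
        control_slope=control_slope, t_ramp=t_ramp, truth=truth,
    ), seed)
    raw_tc = FretTimeCourse(t, raw, T, spec=spec)
    sweep_T = np.linspace(start_T - 5.0, hold_T + 5.0, 101)
    control = FretTimeCourse(
        np.arange(len(sweep_T), dtype=float),
        1.0 + control_slope * (sweep_T - start_T),
        sweep_T,
    )
    return raw_tc, control


def synth_sensorgram(
    kon: float = 1e5,
    koff: float = 3e-4,
    rmax: float = 400.0,
    concentrations=None,
    t_assoc: float = 600.0,
    t_dissoc: float = 600.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    temperature: float | None = None,
) -> list[Sensorgram]:
    """Langmuir sensorgram set with the truth embedded.

    Default concentrations span two decades around KD = koff/kon
    (0.3×, 1×, 3×, 10×, 30× KD).
    """
    kd = koff / kon
    if concentrations is None:
        concentrations = [0.3 * kd, kd, 3 * kd, 10 * kd, 30 * kd]
    grams = simulate_sensorgram(kon, koff, rmax, concentrations, t_assoc,
                                t_dissoc, noise_sd, seed,
                                temperature=temperature)
    spec = GeneratorSpec("sensorgram", dict(
        kon=kon, koff=koff, rmax=rmax, KD=kd,
        concentrations=list(map(float, concentrations)),
        t_assoc=t_assoc, t_dissoc=t_dissoc, noise_sd=noise_sd,
    ), seed)
    for g in grams:
        g.spec = spec
    return grams
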