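"""Synthetic fly-trajectory generator with known ground-truth asymmetry.

Single flies follow a correlated random walk in a circular arena: on each
moving frame the heading changes by a Normal(b_i, turn_noise^2) increment,
where b_i is the fly's fixed turning bias (degrees/step) drawn from a
population with mean ``mu_pop`` and between-fly SD ``sigma_ind``. Step
lengths are truncated-normal, pauses occur with a per-frame probability, and
the heading reflects specularly off the arena wall so positions never leave
the disk. Wing-opening bouts start as a memoryless per-frame process, last a
geometric number of frames, and open the right wing with a per-fly
probability p_i (logit-normal across flies).

Dyads add two couplings on top of the independent walks: a weak steering of
each fly toward its partner when the pair is apart (``dyad_attraction``),
and, in female-male dyads, an extra steering of the male toward the female's
bearing offset by ``position_side_bias_lambda`` degrees (``follow_gain``),
which places the female near Position +lambda in the male's egocentric frame
and the male near +/-180 in the female's.

This generator reproduces the *structure* of the study design (population
vs. individual turning bias, per-fly wing-side preference, chasing geometry
in mixed-sex dyads), not fly biomechanics; see docs/methods.md for the
calibration of the default parameters and for what the emulation leaves out.

All randomness derives from one root seed via ``numpy`` ``SeedSequence``
spawning, one child per fly in emission order, so any single fly can be
re-simulated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .track_data import ArenaConfig, FlyMeta, Track

#: Individuals tested per strain, sex and social context in the study design
#: (single females/males and female-female, male-male, female-male dyads).
#: Dyad columns count individuals, two per arena. Total: 3,519.
TABLE1_DESIGN: dict[str, dict[str, int]] = {
    "RAL-69": {"F": 99, "M": 100, "FF": 152, "MM": 156, "FM": 216},
    "RAL-136": {"F": 100, "M": 100, "FF": 150, "MM": 196, "FM": 188},
    "RAL-338": {"F": 100, "M": 100, "FF": 180, "MM": 138, "FM": 200},
    "RAL-535": {"F": 100, "M": 100, "FF": 160, "MM": 154, "FM": 160},
    "RAL-796": {"F": 100, "M": 100, "FF": 160, "MM": 160, "FM": 150},
}


#: Per-strain dyadic modulation accompanying the packaged design: the
#: genotypes differ in how strongly the dyad context amplifies individual
#: turning asymmetry (strongest in the two strains with pronounced
#: courtship-like following, weakest in the two that lack it). Values are
#: multipliers applied on top of ``SimConfig.dyad_sigma_boost`` = 1 base;
#: chosen once to give the emulated study a strain-by-context structure.
TABLE1_STRAIN_OVERRIDES: dict[str, dict] = {
    "RAL-69": {"dyad_sigma_boost": 1.5},
    "RAL-136": {"dyad_sigma_boost": 2.0},
    "RAL-338": {"dyad_sigma_boost": 1.9},
    "RAL-535": {"dyad_sigma_boost": 1.3},
    "RAL-796": {"dyad_sigma_boost": 1.4},
}


def design_total(design: dict[str, dict[str, int]]) -> int:
    """Total number of individual flies in a design table."""
    return int(sum(sum(row.values()) for row in design.values()))


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Angles are degrees, lengths mm, rates per frame. The defaults emulate
    the study conditions: 10 fps, 60-minute trials, 25.4 mm arenas, no
    population-level turning bias to speak of but substantial between-fly
    bias spread, which is larger for flies tested in dyads.
    """

    seed: int
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    mu_pop: float = 0.02  # population-mean turning bias, deg/step
    sigma_ind: float = 4.9  # between-fly SD of turning bias, deg/step
    dyad_sigma_boost: float = 1.65  # sigma_ind multiplier for flies in dyads
    turn_noise: float = 15.0  # within-fly SD of heading increments, deg/step
    speed_mean: float = 4.0  # mm/s
    speed_sd: float = 2.0  # mm/s
    pause_prob: float = 0.3  # per-frame probability of zero displacement
    wing_event_rate: float = 0.05  # per-frame bout-start probability
    wing_bout_mean: float = 5.0  # mean bout duration, frames
    wing_side_mu: float = 0.0  # logit-scale mean of per-fly P(right wing)
    wing_side_sigma: float = 0.1  # logit-scale SD across flies
    wing_angle: float = 60.0  # opening angle during a bout, deg
    dyad_attraction: float = 0.05  # heading pull toward partner, 0-1
    follow_gain: float = 0.3  # male-toward-female pull in FM dyads, 0-1
    position_side_bias_lambda: float = 0.0  # injected follower bearing offset, deg
    contact_dist: float = 2.5  # mm; attraction applies only beyond this

    def __post_init__(self) -> None:
        for name in ("pause_prob", "wing_event_rate", "dyad_attraction", "follow_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_ind", "turn_noise", "speed_sd", "wing_side_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.wing_bout_mean < 1:
            raise ConfigError("wing_bout_mean must be >= 1 frame")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def sample_individual_biases(
    mu_pop: float, sigma_ind: float, n: int, seed
) -> np.ndarray:
    """Per-fly turning biases b_i ~ Normal(mu_pop, sigma_ind^2), deg/step."""
    rng = np.random.default_rng(_as_seedseq(seed))
    return rng.normal(mu_pop, sigma_ind, size=n)


def sample_wing_side_probs(
    wing_side_mu: float, wing_side_sigma: float, n: int, seed
) -> np.ndarray:
    """Per-fly right-wing probabilities p_i, logit-normal across flies."""
    rng = np.random.default_rng(_as_seedseq(seed))
    logits = rng.normal(wing_side_mu, wing_side_sigma, size=n)
    return 1.0 / (1.0 + np.exp(-logits))


def _truncated_normal(rng, mu: float, sigma: float, size: int) -> np.ndarray:
    """Normal(mu, sigma^2) truncated to >= 0, by redrawing negatives."""
    x = rng.normal(mu, sigma, size=size)
    if sigma == 0:
        return np.maximum(x, 0.0)
    for _ in range(100):
        neg = x < 0
        if not np.any(neg):
            break
        x[neg] = rng.normal(mu, sigma, size=int(neg.sum()))
    np.maximum(x, 0.0, out=x)
    return x


def _wrap180(a: np.ndarray) -> np.ndarray:
    return np.mod(a + 180.0, 360.0) - 180.0


def _draw_motion(rng, n_frames: int, b: float, cfg: SimConfig):
    """Pre-draw one fly's randomness: initial state and per-step arrays.

    The draw order is part of the seeding contract: initial position and
    heading, then heading increments, step lengths and pause indicators for
    the n_frames - 1 steps.
    """
    r = cfg.arena.radius
    u = rng.random()
    th = rng.random() * 360.0
    rad = 0.95 * r * np.sqrt(u)
    x0 = rad * np.cos(np.radians(th))
    y0 = rad * np.sin(np.radians(th))
    h0 = rng.random() * 360.0
    T = n_frames - 1
    dh = rng.normal(b, cfg.turn_noise, size=T)
    steps = _truncated_normal(
        rng, cfg.speed_mean / cfg.arena.fps, cfg.speed_sd / cfg.arena.fps, T
    )
    move = rng.random(T) >= cfg.pause_prob
    return x0, y0, h0, dh, steps, move


def _advance(x, y, h, step, r):
    """One step of the walk for a vector of flies, with specular reflection.

    ``h`` is the heading (deg) after this frame's turning; flies with
    ``step == 0`` stay put. Returns updated (x, y, h); reflected flies exit
    with the reflected heading.
    """
    hr = np.radians(h)
    dx = step * np.cos(hr)
    dy = step * np.sin(hr)
    nx = x + dx
    ny = y + dy
    out = nx * nx + ny * ny > r * r
    if np.any(out):
        nrm = np.hypot(nx[out], ny[out])
        ux = nx[out] / nrm
        uy = ny[out] / nrm
        vdotn = dx[out] * ux + dy[out] * uy
        rdx = dx[out] - 2.0 * vdotn * ux
        rdy = dy[out] - 2.0 * vdotn * uy
        cx = x[out] + rdx
        cy = y[out] + rdy
        rr = np.hypot(cx, cy)
        bad = rr > r
        if np.any(bad):
            scale = (r * (1.0 - 1e-9)) / rr[bad]
            cx[bad] *= scale
            cy[bad] *= scale
        nx[out] = cx
        ny[out] = cy
        h = h.copy()
        h[out] = np.degrees(np.arctan2(rdy, rdx))
    return nx, ny, np.mod(h, 360.0)


def _integrate_independent(x0, y0, h0, dh, steps, move, r):
    """Integrate independent walks. Inputs are (n,) / (n, T) arrays.

    Returns positions and headings of shape (n, T+1).
    """
    n, T = dh.shape
    x = np.empty((n, T + 1))
    y = np.empty((n, T + 1))
    hh = np.empty((n, T + 1))
    x[:, 0], y[:, 0], hh[:, 0] = x0, y0, np.mod(h0, 360.0)
    cx, cy, ch = x[:, 0].copy(), y[:, 0].copy(), hh[:, 0].copy()
    for t in range(T):
        m = move[:, t]
        ch = np.where(m, np.mod(ch + dh[:, t], 360.0), ch)
        cx, cy, ch = _advance(cx, cy, ch, np.where(m, steps[:, t], 0.0), r)
        x[:, t + 1], y[:, t + 1], hh[:, t + 1] = cx, cy, ch
    return x, y, hh


def _integrate_dyads(fa, fb, cfg: SimConfig, follower_b: np.ndarray, lam: np.ndarray):
    """Integrate coupled pairs. ``fa``/``fb`` are per-member pre-drawn arrays
    as returned (stacked) by :func:`_draw_motion`; ``follower_b`` marks dyads
    whose B member chases A (female-male dyads, B = male)."""
    (xa0, ya0, ha0, dha, sta, mva) = fa
    (xb0, yb0, hb0, dhb, stb, mvb) = fb
    n, T = dha.shape
    r = cfg.arena.radius
    out = {
        "xa": np.empty((n, T + 1)), "ya": np.empty((n, T + 1)), "ha": np.empty((n, T + 1)),
        "xb": np.empty((n, T + 1)), "yb": np.empty((n, T + 1)), "hb": np.empty((n, T + 1)),
    }
    xa, ya, ha = xa0.copy(), ya0.copy(), np.mod(ha0, 360.0)
    xb, yb, hb = xb0.copy(), yb0.copy(), np.mod(hb0, 360.0)
    out["xa"][:, 0], out["ya"][:, 0], out["ha"][:, 0] = xa, ya, ha
    out["xb"][:, 0], out["yb"][:, 0], out["hb"][:, 0] = xb, yb, hb
    couple = cfg.dyad_attraction > 0 or cfg.follow_gain > 0
    for t in range(T):
        ma, mb = mva[:, t], mvb[:, t]
        ha = np.where(ma, np.mod(ha + dha[:, t], 360.0), ha)
        hb = np.where(mb, np.mod(hb + dhb[:, t], 360.0), hb)
        if couple:
            dx = xb - xa
            dy = yb - ya
            dist = np.hypot(dx, dy)
            bear_ab = np.degrees(np.arctan2(dy, dx))
            bear_ba = bear_ab + 180.0
            if cfg.dyad_attraction > 0:
                apart = dist > cfg.contact_dist
                ha = np.where(
                    ma & apart,
                    ha + cfg.dyad_attraction * _wrap180(bear_ab - ha),
                    ha,
                )
                hb = np.where(
                    mb & apart,
                    hb + cfg.dyad_attraction * _wrap180(bear_ba - hb),
                    hb,
                )
            if cfg.follow_gain > 0:
                target = bear_ba - lam
                hb = np.where(
                    mb & follower_b & (dist > 0),
                    hb + cfg.follow_gain * _wrap180(target - hb),
                    hb,
                )
        xa, ya, ha = _advance(xa, ya, ha, np.where(ma, sta[:, t], 0.0), r)
        xb, yb, hb = _advance(xb, yb, hb, np.where(mb, stb[:, t], 0.0), r)
        out["xa"][:, t + 1], out["ya"][:, t + 1], out["ha"][:, t + 1] = xa, ya, ha
        out["xb"][:, t + 1], out["yb"][:, t + 1], out["hb"][:, t + 1] = xb, yb, hb
    return out


def _simulate_wings(rng, n_frames: int, p_right: float, cfg: SimConfig):
    """Wing-opening bout series for one fly.

    Bouts start as a memoryless per-frame process with probability
    ``wing_event_rate``, last a geometric number of frames (mean
    ``wing_bout_mean``), and open one wing to ``wing_angle`` degrees; the
    side is right with probability ``p_right``, drawn independently per bout.
    """
    wl = np.zeros(n_frames)
    wr = np.zeros(n_frames)
    rate = cfg.wing_event_rate
    if rate <= 0:
        return wl, wr
    p_dur = 1.0 / cfg.wing_bout_mean
    t = 0
    while True:
        gap = int(rng.geometric(rate))
        start = t + gap - 1
        if start >= n_frames:
            break
        dur = int(rng.geometric(p_dur))
        end = min(start + dur, n_frames)
        if rng.random() < p_right:
            wr[start:end] = cfg.wing_angle
        else:
            wl[start:end] = cfg.wing_angle
        t = start + dur + 1
        if t >= n_frames:
            break
    return wl, wr


def _stack_motion(rngs, n_frames: int, biases, cfg: SimConfig):
    cols = [_draw_motion(rng, n_frames, b, cfg) for rng, b in zip(rngs, biases)]
    x0 = np.array([c[0] for c in cols])
    y0 = np.array([c[1] for c in cols])
    h0 = np.array([c[2] for c in cols])
    dh = np.stack([c[3] for c in cols])
    st = np.stack([c[4] for c in cols])
    mv = np.stack([c[5] for c in cols])
    return x0, y0, h0, dh, st, mv


def _make_track(fly_id, x, y, h, wl, wr, fps) -> Track:
    n = x.size
    frames = np.arange(n, dtype=np.int64)
    return Track(
        fly_id=fly_id,
        frame=frames,
        t=frames / fps,
        x=x,
        y=y,
        heading=h,
        wing_left=wl,
        wing_right=wr,
    )


def simulate_single_fly(cfg: SimConfig, b_i: float, p_i: float, seed) -> Track:
    """Simulate one solitary fly with turning bias ``b_i`` and right-wing
    probability ``p_i``."""
    if cfg.arena.n_frames < 2:
        raise ConfigError("need at least 2 frames")
    rng = np.random.default_rng(_as_seedseq(seed))
    motion = _stack_motion([rng], cfg.arena.n_frames, [b_i], cfg)
    x, y, h = _integrate_independent(*motion, cfg.arena.radius)
    wl, wr = _simulate_wings(rng, cfg.arena.n_frames, p_i, cfg)
    return _make_track("sim_single", x[0], y[0], h[0], wl, wr, cfg.arena.fps)


def simulate_positions(
    cfg: SimConfig, n: int, seed, biases: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fast batch path: positions only, for simulation studies.

    Returns x, y arrays of shape (n, n_frames). Wing bouts are not
    simulated. Unlike the Track-emitting APIs (which spawn one seed child
    per fly so any fly is re-simulable alone), this path draws all flies'
    randomness from a single generator for speed; determinism under the root
    seed still holds exactly.
    """
    rng = np.random.default_rng(_as_seedseq(seed))
    if biases is None:
        biases = rng.normal(cfg.mu_pop, cfg.sigma_ind, size=n)
    biases = np.asarray(biases, dtype=float)
    n_frames = cfg.arena.n_frames
    T = n_frames - 1
    r = cfg.arena.radius
    u = rng.random(n)
    th = rng.random(n) * 360.0
    rad = 0.95 * r * np.sqrt(u)
    x0 = rad * np.cos(np.radians(th))
    y0 = rad * np.sin(np.radians(th))
    h0 = rng.random(n) * 360.0
    dh = rng.normal(biases[:, None], cfg.turn_noise, size=(n, T))
    steps = _truncated_normal(
        rng, cfg.speed_mean / cfg.arena.fps, cfg.speed_sd / cfg.arena.fps, n * T
    ).reshape(n, T)
    move = rng.random((n, T)) >= cfg.pause_prob
    x, y, _ = _integrate_independent(x0, y0, h0, dh, steps, move, r)
    return x, y


def simulate_dyad(
    cfg: SimConfig,
    context: str,
    seed,
    biases: tuple[float, float] | None = None,
    p_rights: tuple[float, float] | None = None,
) -> tuple[Track, Track]:
    """Simulate one dyad; in FM dyads member A is the female, B the male
    (the follower)."""
    if context not in ("FF", "MM", "FM"):
        raise ConfigError(f"dyad context must be FF, MM or FM, got {context!r}")
    ss = _as_seedseq(seed)
    ca, cb, caux = ss.spawn(3)
    rng_a = np.random.default_rng(ca)
    rng_b = np.random.default_rng(cb)
    aux = np.random.default_rng(caux)
    if biases is None:
        sig = cfg.sigma_ind * cfg.dyad_sigma_boost
        biases = tuple(aux.normal(cfg.mu_pop, sig, size=2))
    if p_rights is None:
        p_rights = tuple(
            1.0 / (1.0 + np.exp(-aux.normal(cfg.wing_side_mu, cfg.wing_side_sigma, 2)))
        )
    n_frames = cfg.arena.n_frames
    fa = _stack_motion([rng_a], n_frames, [biases[0]], cfg)
    fb = _stack_motion([rng_b], n_frames, [biases[1]], cfg)
    follower = np.array([context == "FM"])
    lam = np.array([cfg.position_side_bias_lambda])
    res = _integrate_dyads(fa, fb, cfg, follower, lam)
    wla, wra = _simulate_wings(rng_a, n_frames, p_rights[0], cfg)
    wlb, wrb = _simulate_wings(rng_b, n_frames, p_rights[1], cfg)
    fps = cfg.arena.fps
    tr_a = _make_track("sim_dyad_a", res["xa"][0], res["ya"][0], res["ha"][0], wla, wra, fps)
    tr_b = _make_track("sim_dyad_b", res["xb"][0], res["yb"][0], res["hb"][0], wlb, wrb, fps)
    return tr_a, tr_b


@dataclass
class SimExperiment:
    """Result of :func:`simulate_experiment`."""

    tracks: dict[str, Track]
    meta: dict[str, FlyMeta]
    ground_truth: pd.DataFrame
    config: SimConfig


def _dyad_members(context: str) -> tuple[str, str]:
    return {"FF": ("F", "F"), "MM": ("M", "M"), "FM": ("F", "M")}[context]


def simulate_experiment(
    design: dict[str, dict[str, int]],
    cfg: SimConfig,
    seed=None,
    strain_overrides: dict[str, dict] | None = None,
) -> SimExperiment:
    """Simulate a full experiment from a design table.

    ``design`` maps strain -> context -> number of *individuals* (dyad
    contexts therefore need even counts). ``strain_overrides`` maps strain
    names to SimConfig field overrides, to emulate strain-dependent
    interaction differences. The root seed defaults to ``cfg.seed``.
    """
    seed = cfg.seed if seed is None else seed
    root = _as_seedseq(seed)
    plan: list[tuple[str, str, int]] = []  # (strain, context, n_individuals)
    for strain in design:
        for context, count in design[strain].items():
            if count < 0:
                raise ConfigError(f"negative count for {strain}/{context}")
            if context in ("FF", "MM", "FM") and count % 2:
                raise ConfigError(
                    f"{strain}/{context}: dyad context needs an even individual count"
                )
            plan.append((strain, context, int(count)))
    total = sum(n for _, _, n in plan)
    children = iter(root.spawn(total + len(plan)))
    tracks: dict[str, Track] = {}
    meta: dict[str, FlyMeta] = {}
    gt_rows: list[dict] = []
    arena_counter = 0
    n_frames = cfg.arena.n_frames
    for strain, context, count in plan:
        scfg = cfg
        if strain_overrides and strain in strain_overrides:
            scfg = cfg.replace(**strain_overrides[strain])
        group_seed = next(children)
        if count == 0:
            continue
        if context in ("F", "M"):
            fly_seeds = [next(children) for _ in range(count)]
            aux = np.random.default_rng(group_seed)
            biases = aux.normal(scfg.mu_pop, scfg.sigma_ind, size=count)
            p_rights = 1.0 / (
                1.0 + np.exp(-aux.normal(scfg.wing_side_mu, scfg.wing_side_sigma, count))
            )
            chunk = max(1, int(6_000_000 // max(n_frames, 1)))
            for lo in range(0, count, chunk):
                hi = min(lo + chunk, count)
                rngs = [np.random.default_rng(s) for s in fly_seeds[lo:hi]]
                motion = _stack_motion(rngs, n_frames, biases[lo:hi], scfg)
                x, y, h = _integrate_independent(*motion, scfg.arena.radius)
                for j, i in enumerate(range(lo, hi)):
                    fid = f"{strain}_{context}_{i:03d}"
                    arena_counter += 1
                    wl, wr = _simulate_wings(rngs[j], n_frames, p_rights[i], scfg)
                    tracks[fid] = _make_track(fid, x[j], y[j], h[j], wl, wr, scfg.arena.fps)
                    meta[fid] = FlyMeta(fid, f"arena_{arena_counter:04d}", strain, context, context, "")
                    gt_rows.append(
                        dict(fly_id=fid, b_i_deg_per_step=biases[i], p_right=p_rights[i],
                             role="single", lambda_deg=0.0)
                    )
        else:
            n_dyads = count // 2
            sex_a, sex_b = _dyad_members(context)
            fly_seeds = [next(children) for _ in range(count)]
            aux = np.random.default_rng(group_seed)
            sig = scfg.sigma_ind * scfg.dyad_sigma_boost
            biases = aux.normal(scfg.mu_pop, sig, size=count)
            p_rights = 1.0 / (
                1.0 + np.exp(-aux.normal(scfg.wing_side_mu, scfg.wing_side_sigma, count))
            )
            chunk = max(1, int(3_000_000 // max(n_frames, 1)))
            for lo in range(0, n_dyads, chunk):
                hi = min(lo + chunk, n_dyads)
                idx_a = [2 * d for d in range(lo, hi)]
                idx_b = [2 * d + 1 for d in range(lo, hi)]
                rngs_a = [np.random.default_rng(fly_seeds[i]) for i in idx_a]
                rngs_b = [np.random.default_rng(fly_seeds[i]) for i in idx_b]
                fa = _stack_motion(rngs_a, n_frames, biases[idx_a], scfg)
                fb = _stack_motion(rngs_b, n_frames, biases[idx_b], scfg)
                m = hi - lo
                follower = np.full(m, context == "FM")
                lam = np.full(m, scfg.position_side_bias_lambda)
                res = _integrate_dyads(fa, fb, scfg, follower, lam)
                for j, d in enumerate(range(lo, hi)):
                    ia, ib = 2 * d, 2 * d + 1
                    fid_a = f"{strain}_{context}_{d:03d}a"
                    fid_b = f"{strain}_{context}_{d:03d}b"
                    arena_counter += 1
                    arena = f"arena_{arena_counter:04d}"
                    wla, wra = _simulate_wings(rngs_a[j], n_frames, p_rights[ia], scfg)
                    wlb, wrb = _simulate_wings(rngs_b[j], n_frames, p_rights[ib], scfg)
                    tracks[fid_a] = _make_track(
                        fid_a, res["xa"][j], res["ya"][j], res["ha"][j], wla, wra, scfg.arena.fps
                    )
                    tracks[fid_b] = _make_track(
                        fid_b, res["xb"][j], res["yb"][j], res["hb"][j], wlb, wrb, scfg.arena.fps
                    )
                    meta[fid_a] = FlyMeta(fid_a, arena, strain, sex_a, context, fid_b)
                    meta[fid_b] = FlyMeta(fid_b, arena, strain, sex_b, context, fid_a)
                    role_b = "follower" if context == "FM" else "member"
                    role_a = "leader" if context == "FM" else "member"
                    gt_rows.append(
                        dict(fly_id=fid_a, b_i_deg_per_step=biases[ia], p_right=p_rights[ia],
                             role=role_a, lambda_deg=0.0)
                    )
                    gt_rows.append(
                        dict(fly_id=fid_b, b_i_deg_per_step=biases[ib], p_right=p_rights[ib],
                             role=role_b, lambda_deg=float(scfg.position_side_bias_lambda))
                    )
    gt = pd.DataFrame(
        gt_rows, columns=["fly_id", "b_i_deg_per_step", "p_right", "role", "lambda_deg"]
    )
    return SimExperiment(tracks=tracks, meta=meta, ground_truth=gt, config=cfg)
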