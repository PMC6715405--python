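"""Exact stochastic simulation of the spatial chemical master equation.

Each voxel of a :class:`~svbsim.geometry.LatticeGeometry` is a well-mixed
compartment holding integer molecule counts. Three kinds of events occur:

* **reactions** fire within a voxel at mass-action propensities
  (region-restricted channels have propensity 0 outside their region);
* **passive diffusion**: a molecule of species ``s`` hops toward each
  in-domain face neighbor at rate ``D_s`` per molecule per direction;
* **facilitated longitudinal transport**: an immobile carrier adds
  ``alpha * n_carrier * n_cargo`` to the cargo's longitudinal movement
  propensity (split over the two z-faces, or entirely basipetal).

The sampler is an exact next-subvolume-style direct method: per-voxel
total propensities are kept in a Fenwick (binary indexed) tree; each
event draws an exponential waiting time from the global total, descends
the tree to pick a voxel, then re-enumerates that voxel's channels in a
fixed order to pick one. A single seeded xoshiro256++ generator drives
the whole run and its state is checkpointable, so a run can be stopped
and continued at any point and the continuation is event-for-event
identical to an uninterrupted run.

For a cargo molecule leaving an interior 3D voxel, the probability that
the hop is longitudinal is::

    P(up/down) = (2 D + alpha * nP) / (6 D + alpha * nP)
               = 1/3 + (2/3) * nP / (6 D / alpha + nP)

i.e. Michaelis-Menten above the passive baseline 1/3, with Vmax = 2/3
and Km = 6 D / alpha (see :func:`longitudinal_move_probability`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .geometry import DOWN_DIR, UP_DIR, LatticeGeometry, build_cylinder, build_disc
from .network import (
    ALL,
    BASIPETAL_ONLY,
    ReactionNetwork,
    Reaction,
    Species,
    TransportRule,
)
from .geometry import REGION_CODES

__all__ = [
    "StateField",
    "TrajectorySnapshot",
    "longitudinal_move_probability",
    "movement_propensities",
    "run",
    "resume",
    "save_checkpoint",
    "load_checkpoint",
    "config_hash",
    "network_to_dict",
    "network_from_dict",
]

_MASK64 = (1 << 64) - 1
_DIR_NAMES = ("-x", "+x", "-y", "+y", "-z", "+z")


# --------------------------------------------------------------------------
# Analytic transport law
# --------------------------------------------------------------------------

def longitudinal_move_probability(carrier_count, D_cargo, alpha):
    """Probability that a cargo molecule leaving an interior voxel moves
    longitudinally, given the carrier count in that voxel.

    Returns ``(2 D + alpha n) / (6 D + alpha n)``: 1/3 with no carrier,
    saturating toward 1 as the facilitated component dominates.
    """
    carrier_count = np.asarray(carrier_count, dtype=np.float64)
    if D_cargo <= 0:
        raise ValueError("D_cargo must be > 0 (denominator degenerate)")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if np.any(carrier_count < 0):
        raise ValueError("carrier_count must be >= 0")
    out = (2.0 * D_cargo + alpha * carrier_count) / (
        6.0 * D_cargo + alpha * carrier_count
    )
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# State containers
# --------------------------------------------------------------------------

@dataclass
class StateField:
    """Integer molecule counts per species per voxel at one instant."""

    geometry: LatticeGeometry
    species: tuple
    counts: np.ndarray  # (n_voxels, n_species) int64
    time: float = 0.0
    events: int = 0

    def species_counts(self, name: str) -> np.ndarray:
        """Per-voxel counts of one species (a view, not a copy)."""
        return self.counts[:, self.species.index(name)]

    def total(self, name: str | None = None) -> int:
        if name is None:
            return int(self.counts.sum())
        return int(self.species_counts(name).sum())

    def copy(self) -> "StateField":
        return replace(self, counts=self.counts.copy())


@dataclass
class TrajectorySnapshot:
    """A seeded trajectory: snapshots, final state, and resume handles."""

    network: ReactionNetwork
    geometry: LatticeGeometry
    config: dict
    config_hash: str
    times: list
    fields: list  # full count arrays, one per snapshot time
    final: StateField
    rng_state: np.ndarray  # xoshiro256++ state, uint64[4]
    pending_time: float = -1.0  # next event time drawn but not yet executed
    event_log: dict | None = None
    absorbed: bool = False
    # incremental sampler state (per-voxel totals + Fenwick tree): carried
    # so a resumed run replays the identical float operations
    tree_avox: np.ndarray | None = None
    tree_fen: np.ndarray | None = None

    def snapshot_states(self):
        """Iterate snapshots as StateField objects."""
        for t, c in zip(self.times, self.fields):
            yield StateField(self.geometry, self.network.species_names, c, t)


# --------------------------------------------------------------------------
# Network / config serialization and hashing
# --------------------------------------------------------------------------

def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "name": network.name,
        "species": [[s.name, s.diffusion] for s in network.species],
        "reactions": [
            {
                "label": r.label,
                "reactants": dict(sorted(r.reactants.items())),
                "products": dict(sorted(r.products.items())),
                "rate": r.rate,
                "region": r.region,
            }
            for r in network.reactions
        ],
        "transport": [
            {
                "carrier": t.carrier,
                "cargo": t.cargo,
                "alpha": t.alpha,
                "directionality": t.directionality,
            }
            for t in network.transport
        ],
    }


def network_from_dict(d: dict) -> ReactionNetwork:
    return ReactionNetwork(
        species=tuple(Species(n, float(dd)) for n, dd in d["species"]),
        reactions=tuple(
            Reaction(r["label"], dict(r["reactants"]), dict(r["products"]),
                     float(r["rate"]), r.get("region", ALL))
            for r in d["reactions"]
        ),
        transport=tuple(
            TransportRule(t["carrier"], t["cargo"], float(t["alpha"]),
                          t["directionality"])
            for t in d["transport"]
        ),
        name=d.get("name", "custom"),
    )


def _geometry_params(geometry: LatticeGeometry) -> dict:
    return {
        "dimensionality": geometry.dimensionality,
        "radius": geometry.radius,
        "height": geometry.height,
        "shell_fraction": geometry.shell_fraction,
    }


def _geometry_from_params(p: dict) -> LatticeGeometry:
    if int(p["dimensionality"]) == 2:
        return build_disc(int(p["radius"]), float(p["shell_fraction"]))
    return build_cylinder(int(p["radius"]), int(p["height"]),
                          float(p["shell_fraction"]))


def config_hash(network: ReactionNetwork, geometry: LatticeGeometry,
                seed: int) -> str:
    """Hash of the semantic run identity: system, domain, and seed.

    Stop conditions and snapshot cadence are deliberately excluded so a
    checkpoint can be resumed with a longer stop; any change to a rate
    constant, species, region, geometry or seed changes the hash.
    """
    payload = {
        "network": network_to_dict(network),
        "geometry": _geometry_params(geometry),
        "seed": int(seed),
    }
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


# --------------------------------------------------------------------------
# RNG seeding (xoshiro256++, state seeded via splitmix64)
# --------------------------------------------------------------------------

def _seed_rng_state(seed: int) -> np.ndarray:
    x = int(seed) & _MASK64
    out = np.empty(4, dtype=np.uint64)
    for i in range(4):
        x = (x + 0x9E3779B97F4A7C15) & _MASK64
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        z ^= z >> 31
        out[i] = z
    if not out.any():
        out[0] = 1
    return out


@njit(inline="always")
def _rotl(x, k):
    return (x << k) | (x >> (np.uint64(64) - k))


@njit(inline="always")
def _rand_u01(state):
    # xoshiro256++ step, then take 53 high bits as a double in [0, 1)
    s0 = state[0]
    s1 = state[1]
    s2 = state[2]
    s3 = state[3]
    result = _rotl(s0 + s3, np.uint64(23)) + s0
    t = s1 << np.uint64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, np.uint64(45))
    state[0] = s0
    state[1] = s1
    state[2] = s2
    state[3] = s3
    return (result >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# --------------------------------------------------------------------------
# Main event loop
# --------------------------------------------------------------------------
# The propensity bookkeeping and channel arithmetic live as closures
# inside _advance: numba's closure inlining flattens them into the event
# loop, which matters here — a real function call with several array
# arguments costs more than the event arithmetic itself.
#
# Voxel selection uses a Fenwick (binary indexed) tree over per-voxel
# propensity totals, updated incrementally per event. The tree's float
# content therefore depends on the event history, not just the current
# state; to keep checkpoint/resume bit-identical to an uninterrupted
# run, the tree and the per-voxel totals are carried in the checkpoint
# and restored on resume, and the periodic drift-correcting rebuild is
# pinned to absolute event counts so both paths rebuild at the same
# events.

_STOP_LIMIT = 0     # hit max_events or max_time
_STOP_ABSORBED = 1  # total propensity vanished


@njit(cache=True)
def _advance(counts, nbrs, deg, regionbits,
             D, carr, alpha, basip,
             r_rate, r_sp, r_st, r_regbit, r_delta,
             state, scalars, avox_io, fen_io,
             max_time, max_events,
             log_t, log_vox, log_code, log_dest, log_len):
    """Run events until a stop bound.

    scalars = [t, events, pending_t, tree_initialized]; avox_io and
    fen_io are the per-voxel totals and Fenwick tree, owned by the
    caller so their float state survives segment boundaries and
    checkpoints. They are copied to locals here (and written back on
    exit) so the optimizer can prove the hot loop's arrays don't alias.
    """
    n_v, n_s = counts.shape
    n_r = r_rate.shape[0]
    avox = avox_io.copy()
    fen = fen_io.copy()
    fen_hi = 1
    while (fen_hi << 1) <= n_v:
        fen_hi <<= 1

    def fen_update(i, delta):
        i += 1
        while i <= n_v:
            fen[i] += delta
            i += i & (-i)

    def fen_total():
        tot = 0.0
        i = n_v
        while i > 0:
            tot += fen[i]
            i -= i & (-i)
        return tot

    def rxn_prop(v, r):
        bit = r_regbit[r]
        if bit != 0 and (regionbits[v] & bit) == 0:
            return 0.0
        a = r_rate[r]
        for k in range(2):
            sp = r_sp[r, k]
            if sp >= 0:
                m = counts[v, sp]
                if r_st[r, k] == 1:
                    a *= m
                else:
                    a *= m * (m - 1)
        if a > 0.0:
            return a
        return 0.0

    def voxel_total(v):
        a = 0.0
        for r in range(n_r):
            a += rxn_prop(v, r)
        for sp in range(n_s):
            m = counts[v, sp]
            if m > 0:
                if D[sp] > 0.0:
                    a += D[sp] * m * deg[v]
                c = carr[sp]
                if c >= 0 and alpha[sp] > 0.0:
                    nP = counts[v, c]
                    if nP > 0:
                        fac = alpha[sp] * nP * m
                        if basip[sp]:
                            if nbrs[v, 4] >= 0:
                                a += fac
                        else:
                            if nbrs[v, 4] >= 0:
                                a += 0.5 * fac
                            if nbrs[v, 5] >= 0:
                                a += 0.5 * fac
        return a

    def update_voxel(v):
        new = voxel_total(v)
        fen_update(v, new - avox[v])
        avox[v] = new

    def refresh():
        for i in range(n_v + 1):
            fen[i] = 0.0
        for v0 in range(n_v):
            avox[v0] = voxel_total(v0)
            fen_update(v0, avox[v0])

    if scalars[3] == 0.0:
        refresh()
        scalars[3] = 1.0

    t = scalars[0]
    ev = int(scalars[1])
    pending = scalars[2]
    nlog = int(log_len[0])
    logcap = log_t.shape[0]
    status = _STOP_LIMIT

    while True:
        if ev >= max_events or t >= max_time:
            break
        total = fen_total()
        if total <= 0.0:
            status = _STOP_ABSORBED
            break
        if pending >= 0.0:
            t_next = pending
        else:
            u = _rand_u01(state)
            t_next = t + (-np.log(1.0 - u) / total)
        if t_next > max_time:
            # remember the drawn event time; do not consume the event
            pending = t_next
            t = max_time
            break
        pending = -1.0
        t = t_next

        # descend the Fenwick tree to the voxel covering the target
        target = _rand_u01(state) * total
        v = 0
        bit = fen_hi
        while bit > 0:
            nxt = v + bit
            if nxt <= n_v and fen[nxt] <= target:
                target -= fen[nxt]
                v = nxt
            bit >>= 1
        resid = target
        if v >= n_v:
            v = n_v - 1
            resid = 0.0

        # --- channel selection within voxel v (fixed order) ---
        fired = False
        code = -1
        dest = -1
        # last positive channel, as a guard against float round-off
        lb_code = -1
        lb_dest = -1

        for r in range(n_r):
            a = rxn_prop(v, r)
            if a > 0.0:
                lb_code = r
                lb_dest = -1
                if resid < a:
                    code = r
                    fired = True
                    break
                resid -= a
        if not fired:
            for s in range(n_s):
                n = counts[v, s]
                if n <= 0:
                    continue
                if D[s] > 0.0:
                    a = D[s] * n
                    for d in range(6):
                        u_v = nbrs[v, d]
                        if u_v >= 0:
                            lb_code = n_r + s * 6 + d
                            lb_dest = u_v
                            if resid < a:
                                code = lb_code
                                dest = u_v
                                fired = True
                                break
                            resid -= a
                    if fired:
                        break
                c = carr[s]
                if c >= 0 and alpha[s] > 0.0:
                    nP = counts[v, c]
                    if nP > 0:
                        fac = alpha[s] * nP * n
                        if basip[s]:
                            u_v = nbrs[v, 4]
                            if u_v >= 0:
                                lb_code = n_r + s * 6 + 4
                                lb_dest = u_v
                                if resid < fac:
                                    code = lb_code
                                    dest = u_v
                                    fired = True
                                    break
                                resid -= fac
                        else:
                            half = 0.5 * fac
                            u_v = nbrs[v, 4]
                            if u_v >= 0:
                                lb_code = n_r + s * 6 + 4
                                lb_dest = u_v
                                if resid < half:
                                    code = lb_code
                                    dest = u_v
                                    fired = True
                                    break
                                resid -= half
                            u_v = nbrs[v, 5]
                            if u_v >= 0:
                                lb_code = n_r + s * 6 + 5
                                lb_dest = u_v
                                if resid < half:
                                    code = lb_code
                                    dest = u_v
                                    fired = True
                                    break
                                resid -= half
        if not fired:
            if lb_code < 0:
                # drifted tree entry: this voxel has nothing to fire;
                # refresh it and redraw
                update_voxel(v)
                continue
            code = lb_code
            dest = lb_dest

        # --- apply ---
        if code < n_r:
            for s in range(n_s):
                counts[v, s] += r_delta[code, s]
            update_voxel(v)
        else:
            s = (code - n_r) // 6
            counts[v, s] -= 1
            counts[dest, s] += 1
            update_voxel(v)
            update_voxel(dest)
        ev += 1

        if nlog < logcap:
            log_t[nlog] = t
            log_vox[nlog] = v
            log_code[nlog] = code
            log_dest[nlog] = dest
            nlog += 1

        # drift-correcting rebuild at absolute event counts, so a
        # resumed trajectory rebuilds at the same events as an
        # uninterrupted one
        if ev & 4194303 == 0:
            refresh()

    avox_io[:] = avox
    fen_io[:] = fen
    scalars[0] = t
    scalars[1] = ev
    scalars[2] = pending
    log_len[0] = nlog
    return status


# --------------------------------------------------------------------------
# Kernel compilation from a network + geometry
# --------------------------------------------------------------------------

class _Kernel:
    """Flat-array encoding of a (network, geometry) pair for the njit core."""

    def __init__(self, network: ReactionNetwork, geometry: LatticeGeometry):
        self.network = network
        self.geometry = geometry
        names = network.species_names
        n_s = len(names)
        self.D = network.diffusion_vector()
        self.carr = np.full(n_s, -1, dtype=np.int64)
        self.alpha = np.zeros(n_s, dtype=np.float64)
        self.basip = np.zeros(n_s, dtype=np.bool_)
        for rule in network.transport:
            cg = names.index(rule.cargo)
            self.carr[cg] = names.index(rule.carrier)
            self.alpha[cg] = rule.alpha
            self.basip[cg] = rule.directionality == BASIPETAL_ONLY

        n_r = len(network.reactions)
        self.r_rate = np.zeros(n_r, dtype=np.float64)
        self.r_sp = np.full((n_r, 2), -1, dtype=np.int64)
        self.r_st = np.zeros((n_r, 2), dtype=np.int64)
        self.r_delta = np.zeros((n_r, n_s), dtype=np.int64)
        self.r_regbit = np.zeros(n_r, dtype=np.int64)
        for i, r in enumerate(network.reactions):
            self.r_rate[i] = r.rate
            for k, (sp, st) in enumerate(sorted(r.reactants.items())):
                self.r_sp[i, k] = names.index(sp)
                self.r_st[i, k] = st
            for sp, st in r.reactants.items():
                self.r_delta[i, names.index(sp)] -= st
            for sp, st in r.products.items():
                self.r_delta[i, names.index(sp)] += st
            if r.region != ALL:
                self.r_regbit[i] = 1 << (REGION_CODES[r.region] - 1)

        self.nbrs = geometry.neighbors
        self.deg = geometry.degree().astype(np.float64)
        self.regionbits = geometry.region_labels()
        self.n_r = n_r
        self.n_s = n_s

    def decode_channel(self, code: int):
        """Human-readable description of a logged channel code."""
        if code < self.n_r:
            return ("reaction", self.network.reactions[code].label)
        s, d = divmod(code - self.n_r, 6)
        return ("hop", self.network.species_names[s], _DIR_NAMES[d])


def movement_propensities(state: StateField, network: ReactionNetwork,
                          species_name: str, voxel: int) -> dict:
    """Per-direction movement rates of one species out of one voxel.

    Returns a dict mapping direction names ('-x', '+x', '-y', '+y',
    '-z', '+z') to total (passive + facilitated) rates; directions with
    no in-domain neighbor are absent.
    """
    names = network.species_names
    s = names.index(species_name)
    n = int(state.counts[voxel, s])
    D = network.species[s].diffusion
    out = {}
    nbrs = state.geometry.neighbors[voxel]
    for d in range(6):
        if nbrs[d] >= 0:
            out[_DIR_NAMES[d]] = D * n
    for rule in network.transport:
        if rule.cargo != species_name or rule.alpha == 0:
            continue
        nP = int(state.counts[voxel, names.index(rule.carrier)])
        fac = rule.alpha * nP * n
        if rule.directionality == BASIPETAL_ONLY:
            if nbrs[DOWN_DIR] >= 0:
                out[_DIR_NAMES[DOWN_DIR]] += fac
        else:
            if nbrs[DOWN_DIR] >= 0:
                out[_DIR_NAMES[DOWN_DIR]] += 0.5 * fac
            if nbrs[UP_DIR] >= 0:
                out[_DIR_NAMES[UP_DIR]] += 0.5 * fac
    return out


# --------------------------------------------------------------------------
# Run / resume
# --------------------------------------------------------------------------

class IncompatibleCheckpoint(RuntimeError):
    """Checkpoint config hash does not match the supplied system."""


def _stop_bounds(config: dict, base_time: float, base_events: int):
    max_events = config.get("max_events")
    max_time = config.get("max_time")
    if max_events is None and max_time is None:
        raise ValueError("config must set max_events and/or max_time")
    ev = np.inf if max_events is None else base_events + int(max_events)
    tt = np.inf if max_time is None else base_time + float(max_time)
    if (max_events is not None and int(max_events) < 0) or (
            max_time is not None and float(max_time) < 0):
        raise ValueError("stop bounds must be non-negative")
    return tt, ev


def _drive(kern: _Kernel, counts, scalars, rng_state, avox, fen,
           stop_time, stop_events, snap_dt, snap_dev, times, fields,
           log_arrays):
    """Advance to the stop bound, pausing at snapshot boundaries."""
    log_t, log_vox, log_code, log_dest, log_len = log_arrays
    absorbed = False
    while True:
        t, ev = scalars[0], int(scalars[1])
        seg_t = stop_time
        seg_ev = stop_events
        if snap_dt is not None:
            k = np.floor(t / snap_dt + 1e-9) + 1
            seg_t = min(seg_t, k * snap_dt)
        if snap_dev is not None:
            seg_ev = min(seg_ev, (ev // snap_dev + 1) * snap_dev)
        status = _advance(
            counts, kern.nbrs, kern.deg, kern.regionbits,
            kern.D, kern.carr, kern.alpha, kern.basip,
            kern.r_rate, kern.r_sp, kern.r_st, kern.r_regbit, kern.r_delta,
            rng_state, scalars, avox, fen,
            np.float64(seg_t), np.int64(min(seg_ev, 2**62)),
            log_t, log_vox, log_code, log_dest, log_len)
        t, ev = scalars[0], int(scalars[1])
        if status == _STOP_ABSORBED:
            absorbed = True
            if t > times[-1]:
                times.append(t)
                fields.append(counts.copy())
            break
        hit_snap = (snap_dt is not None and seg_t < stop_time and
                    t >= seg_t - 1e-12) or (
                    snap_dev is not None and seg_ev < stop_events and
                    ev >= seg_ev)
        if t >= stop_time or ev >= stop_events:
            if t > times[-1]:
                times.append(t)
                fields.append(counts.copy())
            break
        if hit_snap and t > times[-1]:
            times.append(t)
            fields.append(counts.copy())
    return absorbed


def run(network: ReactionNetwork, geometry: LatticeGeometry,
        config: dict) -> TrajectorySnapshot:
    """Run a seeded stochastic trajectory from the all-zero initial state.

    Parameters
    ----------
    network, geometry
        The reaction-diffusion system and its domain.
    config : dict
        ``seed`` (required int); ``max_events`` and/or ``max_time`` (at
        least one required); ``snapshot_every_time`` /
        ``snapshot_every_events`` for intermediate snapshots;
        ``event_log`` (bool) with ``event_log_capacity`` to record
        (time, voxel, channel, destination) per event for audits;
        ``initial_counts`` to start from a non-zero state.

    Returns
    -------
    TrajectorySnapshot
        Snapshot sequence (always includes t=0 and the final state),
        final StateField, and the RNG state needed by :func:`resume`.
    """
    if "seed" not in config:
        raise ValueError("config must set a seed")
    seed = int(config["seed"])
    stop_time, stop_events = _stop_bounds(config, 0.0, 0)

    n_v, n_s = geometry.n_voxels, len(network.species)
    counts = np.zeros((n_v, n_s), dtype=np.int64)
    if config.get("initial_counts") is not None:
        init = np.asarray(config["initial_counts"], dtype=np.int64)
        if init.shape != counts.shape or (init < 0).any():
            raise ValueError("initial_counts must be non-negative with shape "
                             f"{counts.shape}")
        counts[:] = init

    rng_state = _seed_rng_state(seed)
    scalars = np.array([0.0, 0.0, -1.0, 0.0], dtype=np.float64)
    kern = _Kernel(network, geometry)
    avox = np.zeros(n_v, dtype=np.float64)
    fen = np.zeros(n_v + 1, dtype=np.float64)

    cap = int(config.get("event_log_capacity", 0)) if config.get("event_log") \
        else 0
    log_arrays = (np.zeros(cap), np.zeros(cap, np.int64),
                  np.zeros(cap, np.int64), np.zeros(cap, np.int64),
                  np.zeros(1, np.int64))

    times = [0.0]
    fields = [counts.copy()]
    absorbed = _drive(kern, counts, scalars, rng_state, avox, fen,
                      stop_time, stop_events,
                      config.get("snapshot_every_time"),
                      config.get("snapshot_every_events"), times, fields,
                      log_arrays)

    final = StateField(geometry, network.species_names, counts,
                       float(scalars[0]), int(scalars[1]))
    event_log = None
    if cap:
        n = int(log_arrays[4][0])
        event_log = {
            "time": log_arrays[0][:n].copy(),
            "voxel": log_arrays[1][:n].copy(),
            "channel": log_arrays[2][:n].copy(),
            "dest": log_arrays[3][:n].copy(),
            "kernel": kern,
        }
    return TrajectorySnapshot(
        network=network, geometry=geometry, config=dict(config),
        config_hash=config_hash(network, geometry, seed),
        times=times, fields=fields, final=final,
        rng_state=rng_state, pending_time=float(scalars[2]),
        event_log=event_log, absorbed=absorbed,
        tree_avox=avox, tree_fen=fen)


def resume(checkpoint: TrajectorySnapshot, additional_stop: dict,
           network: ReactionNetwork | None = None,
           geometry: LatticeGeometry | None = None) -> TrajectorySnapshot:
    """Continue a trajectory past its stop bound.

    ``additional_stop`` gives incremental bounds (``max_events`` and/or
    ``max_time`` beyond the checkpoint). If ``network``/``geometry`` are
    supplied they must hash-match the checkpoint; a mismatch (e.g. an
    altered rate constant) raises :class:`IncompatibleCheckpoint`.
    """
    net = network or checkpoint.network
    geom = geometry or checkpoint.geometry
    seed = int(checkpoint.config["seed"])
    h = config_hash(net, geom, seed)
    if h != checkpoint.config_hash:
        raise IncompatibleCheckpoint(
            "checkpoint was produced by a different system configuration")

    counts = checkpoint.final.counts.copy()
    n_v = geom.n_voxels
    if checkpoint.tree_avox is not None:
        avox = checkpoint.tree_avox.copy()
        fen = checkpoint.tree_fen.copy()
        initialized = 1.0
    else:
        avox = np.zeros(n_v, dtype=np.float64)
        fen = np.zeros(n_v + 1, dtype=np.float64)
        initialized = 0.0
    scalars = np.array([checkpoint.final.time, checkpoint.final.events,
                        checkpoint.pending_time, initialized],
                       dtype=np.float64)
    rng_state = checkpoint.rng_state.copy()
    stop_time, stop_events = _stop_bounds(additional_stop,
                                          checkpoint.final.time,
                                          checkpoint.final.events)
    kern = _Kernel(net, geom)
    cap = 0
    log_arrays = (np.zeros(cap), np.zeros(cap, np.int64),
                  np.zeros(cap, np.int64), np.zeros(cap, np.int64),
                  np.zeros(1, np.int64))
    times = list(checkpoint.times)
    fields = list(checkpoint.fields)
    cfg = dict(checkpoint.config)
    absorbed = _drive(kern, counts, scalars, rng_state, avox, fen,
                      stop_time, stop_events,
                      cfg.get("snapshot_every_time"),
                      cfg.get("snapshot_every_events"), times, fields,
                      log_arrays)
    final = StateField(geom, net.species_names, counts, float(scalars[0]),
                       int(scalars[1]))
    return TrajectorySnapshot(
        network=net, geometry=geom, config=cfg,
        config_hash=checkpoint.config_hash, times=times, fields=fields,
        final=final, rng_state=rng_state, pending_time=float(scalars[2]),
        absorbed=absorbed, tree_avox=avox, tree_fen=fen)


# --------------------------------------------------------------------------
# Checkpoint files (HDF5)
# --------------------------------------------------------------------------

def save_checkpoint(snapshot: TrajectorySnapshot, path) -> None:
    """Persist a trajectory checkpoint (final state + RNG) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = snapshot.config_hash
        f.attrs["time"] = snapshot.final.time
        f.attrs["events"] = snapshot.final.events
        f.attrs["pending_time"] = snapshot.pending_time
        f.attrs["network"] = json.dumps(network_to_dict(snapshot.network))
        f.attrs["geometry"] = json.dumps(_geometry_params(snapshot.geometry))
        f.attrs["config"] = json.dumps(
            {k: v for k, v in snapshot.config.items()
             if isinstance(v, (int, float, str, bool, type(None)))})
        f.create_dataset("counts", data=snapshot.final.counts,
                         compression="gzip")
        f.create_dataset("rng_state", data=snapshot.rng_state)
        f.create_dataset("snapshot_times", data=np.asarray(snapshot.times))
        if snapshot.tree_avox is not None:
            f.create_dataset("tree_avox", data=snapshot.tree_avox)
            f.create_dataset("tree_fen", data=snapshot.tree_fen)


def load_checkpoint(path) -> TrajectorySnapshot:
    """Load a checkpoint written by :func:`save_checkpoint`.

    The network and geometry are reconstructed from their serialized
    descriptions; the stored config hash is preserved so a tampered
    reconstruction is still detected at resume time.
    """
    import h5py

    with h5py.File(path, "r") as f:
        network = network_from_dict(json.loads(f.attrs["network"]))
        geometry = _geometry_from_params(json.loads(f.attrs["geometry"]))
        config = json.loads(f.attrs["config"])
        counts = f["counts"][:]
        rng_state = f["rng_state"][:].astype(np.uint64)
        t = float(f.attrs["time"])
        ev = int(f.attrs["events"])
        pending = float(f.attrs["pending_time"])
        h = str(f.attrs["config_hash"])
        times = [float(x) for x in f["snapshot_times"][:]]
        avox = f["tree_avox"][:] if "tree_avox" in f else None
        fen = f["tree_fen"][:] if "tree_fen" in f else None
    final = StateField(geometry, network.species_names, counts, t, ev)
    return TrajectorySnapshot(
        network=network, geometry=geometry, config=config, config_hash=h,
        times=times, fields=[counts.copy()], final=final,
        rng_state=rng_state, pending_time=pending,
        tree_avox=avox, tree_fen=fen)
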