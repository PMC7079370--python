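"""Discrete-time stochastic agent simulator of the mechanotransduction network.

Agents perform constrained Brownian motion inside nested spherical
compartments, bind to the nearest eligible partner within the interaction
range ``R_inter``, and undergo timer-driven state transitions and
(partial) complex dissociations.  Membrane integrins are static and are
switched on by the square-wave mechanical load.  The recorded output is a
:class:`StateTimeSeries`: per-step counts of every (species, activation,
bound-partner, compartment) label, with positions and velocities discarded.

Update order per step: load coupling, motion, bindings, timers, recording.
Within a step agents are processed in a seeded random permutation; when two
seekers claim the same partner the first in permutation order wins and the
loser skips the step.  Runs are bit-reproducible for a fixed seed.

Timer semantics: a timer is (re)armed when an agent enters a label with
applicable timed rules, drawn uniformly on the rule's support (default
``[0, 2*mean]``).  Personal activation-cycle clocks (state transitions,
which match regardless of bound status) persist across binding and release;
complex clocks live on the carrier agent of the bound pair.  When several
timed rules apply, each is sampled and the earliest wins.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import (SPECIES_SHELLS, STATIC_SPECIES, CompartmentGeometry,
                     ConfigError, MechanicalStimulus, ReactionRule,
                     SimulationConfig, config_hash)
from .labels import ANY, COMPARTMENTS, StateLabel

SPECIES = tuple(SPECIES_SHELLS)
_SP_CODE = {sp: i for i, sp in enumerate(SPECIES)}
_NS = len(SPECIES)
_NCOMP = len(COMPARTMENTS)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def square_wave(t: float | np.ndarray, stim: MechanicalStimulus) -> float | np.ndarray:
    """Square-wave load: magnitude M on the first half period, baseline m0
    on the second; phase 0 means the high phase comes first."""
    frac = np.mod(np.asarray(t, dtype=float) - stim.phase, stim.period)
    out = np.where(frac < 0.5 * stim.period, stim.magnitude, stim.baseline)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def sample_timer(mean: float, support: tuple[float, float] | None,
                 rng: np.random.Generator) -> float:
    """Draw a waiting time uniformly on ``support`` (default [0, 2*mean])."""
    if support is None:
        support = (0.0, 2.0 * mean)
    lo, hi = support
    if hi < lo:
        raise ValueError("timer support hi < lo")
    return float(rng.uniform(lo, hi))


# --------------------------------------------------------------------------
# compiled rule set
# --------------------------------------------------------------------------

def _key(sp: int, act: int, bnd: int) -> int:
    return (sp * 2 + act) * (_NS + 1) + (bnd + 1)


def _label_code(sp: int, act: int, bnd: int, comp: int) -> int:
    return _key(sp, act, bnd) * _NCOMP + comp


N_CODES = _NS * 2 * (_NS + 1) * _NCOMP


def code_to_label(code: int) -> StateLabel:
    comp = code % _NCOMP
    key = code // _NCOMP
    bnd = key % (_NS + 1) - 1
    key //= (_NS + 1)
    act = key % 2
    sp = key // 2
    return StateLabel(
        species=SPECIES[sp],
        activation="active" if act else "inactive",
        bound=None if bnd < 0 else SPECIES[bnd],
        compartment=COMPARTMENTS[comp],
    )


@dataclass
class _CompiledTimed:
    rule_id: int
    kind: str
    lo: float
    hi: float
    # state_transition: (new_sp, new_act); dissociation: carrier and partner
    # (sp, act) plus spawns; production: spawns plus optional nucleus gate
    self_product: tuple[int, int] | None = None
    partner_product: tuple[int, int] | None = None
    spawns: tuple[tuple[int, int], ...] = ()
    nucleus_gated: bool = False


@dataclass
class _CompiledBinding:
    rule_id: int
    name: str
    seek: tuple[int, int]          # (species, activation), unbound
    target: tuple[int, int]
    seek_product: tuple[int, int, int]    # (sp, act, bound_code)
    target_product: tuple[int, int, int]
    forms_complex: bool
    seeker_is_carrier: bool
    range_limited: bool


@dataclass
class RuleSet:
    bindings: list[_CompiledBinding]
    exact: dict[int, list[_CompiledTimed]]        # key(sp, act, bnd)
    loose: dict[tuple[int, int], list[_CompiledTimed]]   # (sp, act)

    def __post_init__(self) -> None:
        self._by_key: dict[int, list[_CompiledTimed]] = {}
        self.by_id: dict[int, _CompiledTimed] = {}
        for lst in (*self.exact.values(), *self.loose.values()):
            for ct in lst:
                self.by_id[ct.rule_id] = ct
        n_ids = max(self.by_id, default=-1) + 1
        self.transition_mask = np.zeros(n_ids + 1, dtype=bool)
        for rid, ct in self.by_id.items():
            self.transition_mask[rid] = ct.kind == "state_transition"

    def applicable(self, sp: int, act: int, bnd: int) -> list[_CompiledTimed]:
        key = _key(sp, act, bnd)
        cached = self._by_key.get(key)
        if cached is None:
            cached = (self.exact.get(key, [])
                      + self.loose.get((sp, act), []))
            self._by_key[key] = cached
        return cached


def _lab_to_sab(lab: StateLabel) -> tuple[int, int, int]:
    sp = _SP_CODE[lab.species]
    act = 1 if lab.activation == "active" else 0
    bnd = -1 if lab.bound is None else _SP_CODE[lab.bound]
    return sp, act, bnd


def compile_rules(rules: tuple[ReactionRule, ...]) -> RuleSet:
    exact: dict[int, list[_CompiledTimed]] = {}
    loose: dict[tuple[int, int], list[_CompiledTimed]] = {}
    bindings: list[_CompiledBinding] = []
    timed: list[tuple[ReactionRule, _CompiledTimed]] = []

    for rid, rule in enumerate(rules):
        if rule.kind == "binding":
            (a, b) = rule.reactant_labels
            (pa, pb) = rule.product_labels
            sa, aa, ba = _lab_to_sab(a)
            sb, ab, bb = _lab_to_sab(b)
            if ba != -1 or bb != -1:
                raise ConfigError(
                    f"rule {rule.name!r}: binding reactants must be unbound")
            psa, paa, pba = _lab_to_sab(pa)
            psb, pab, pbb = _lab_to_sab(pb)
            forms_complex = pba != -1 or pbb != -1
            if forms_complex and (pba == -1 or pbb == -1):
                raise ConfigError(
                    f"rule {rule.name!r}: complex products must both be bound")
            bindings.append(_CompiledBinding(
                rule_id=rid, name=rule.name,
                seek=(sa, aa), target=(sb, ab),
                seek_product=(psa, paa, pba),
                target_product=(psb, pab, pbb),
                forms_complex=forms_complex,
                seeker_is_carrier=False,  # fixed after timers compiled
                range_limited=rule.range_limited))
            continue

        lab = rule.reactant_labels[0]
        sp, act, bnd = _lab_to_sab(lab)
        lo, hi = rule.support
        ct = _CompiledTimed(rule_id=rid, kind=rule.kind, lo=lo, hi=hi)
        if rule.kind == "state_transition":
            psp, pact, pbnd = _lab_to_sab(rule.product_labels[0])
            if pbnd != -1:
                raise ConfigError(
                    f"rule {rule.name!r}: transition product must be unbound")
            ct.self_product = (psp, pact)
            loose.setdefault((sp, act), []).append(ct)
        elif rule.kind == "dissociation":
            if bnd == -1:
                raise ConfigError(
                    f"rule {rule.name!r}: dissociation reactant must be bound")
            prods = [_lab_to_sab(p) for p in rule.product_labels]
            ct.self_product = prods[0][:2]
            ct.partner_product = prods[1][:2]
            ct.spawns = tuple(p[:2] for p in prods[2:])
            exact.setdefault(_key(sp, act, bnd), []).append(ct)
        elif rule.kind == "production":
            prods = [_lab_to_sab(p) for p in rule.product_labels]
            ct.self_product = prods[0][:2]
            ct.spawns = tuple(p[:2] for p in prods[1:])
            ct.nucleus_gated = rule.reactant_labels[0].compartment == "nucleus"
            exact.setdefault(_key(sp, act, bnd), []).append(ct)
        elif rule.kind == "degradation":
            exact.setdefault(_key(sp, act, bnd), []).append(ct)
        timed.append((rule, ct))

    ruleset = RuleSet(bindings=bindings, exact=exact, loose=loose)
    # decide complex carriers: the bound product label that has a
    # dissociation rule is the carrier of the pair's complex clock
    for cb in ruleset.bindings:
        if not cb.forms_complex:
            continue
        seek_has = bool(ruleset.exact.get(_key(*cb.seek_product), []))
        targ_has = bool(ruleset.exact.get(_key(*cb.target_product), []))
        if seek_has and targ_has:
            raise ConfigError(
                f"rule {cb.name!r}: both complex halves own dissociation "
                f"rules; one carrier per complex is required")
        cb.seeker_is_carrier = seek_has
    return ruleset


# --------------------------------------------------------------------------
# simulation state
# --------------------------------------------------------------------------

@dataclass
class SimState:
    """Structure-of-arrays agent state plus RNG and compiled rules."""

    config: SimulationConfig
    time: float
    rng: np.random.Generator
    ruleset: RuleSet
    pos: np.ndarray          # (cap, 3) float64
    species: np.ndarray      # (cap,) int16
    active: np.ndarray       # (cap,) bool
    bound: np.ndarray        # (cap,) int16, partner species or -1
    partner: np.ndarray      # (cap,) int64, partner agent index or -1
    is_carrier: np.ndarray   # (cap,) bool
    alive: np.ndarray        # (cap,) bool
    timer: np.ndarray        # (cap,) float64, remaining seconds (inf none)
    timer_rule: np.ndarray   # (cap,) int16
    n: int                   # number of slots in use (alive or dead)
    load: float = 0.0
    births: int = 0
    deaths: int = 0

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n]))

    def _grow(self, extra: int) -> None:
        cap = len(self.species)
        need = self.n + extra
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        pad = new_cap - cap
        self.pos = np.vstack([self.pos, np.zeros((pad, 3))])
        for name, fill in (("species", 0), ("bound", -1), ("partner", -1),
                           ("timer_rule", -1)):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate(
                [arr, np.full(pad, fill, dtype=arr.dtype)]))
        self.active = np.concatenate([self.active, np.zeros(pad, bool)])
        self.is_carrier = np.concatenate([self.is_carrier, np.zeros(pad, bool)])
        self.alive = np.concatenate([self.alive, np.zeros(pad, bool)])
        self.timer = np.concatenate([self.timer, np.full(pad, np.inf)])

    def rearm(self, idx: int, keep_running: bool = True) -> None:
        """(Re)arm the timer of agent ``idx`` after a label change."""
        sp = int(self.species[idx])
        act = int(self.active[idx])
        bnd = int(self.bound[idx])
        rules = self.ruleset.applicable(sp, act, bnd)
        if not rules:
            self.timer[idx] = np.inf
            self.timer_rule[idx] = -1
            return
        if keep_running and self.timer_rule[idx] >= 0 and np.isfinite(self.timer[idx]):
            if any(ct.rule_id == self.timer_rule[idx] for ct in rules):
                return  # personal clock persists across the label change
        best_t, best_r = np.inf, -1
        for ct in rules:
            t = self.rng.uniform(ct.lo, ct.hi)
            if t < best_t:
                best_t, best_r = t, ct.rule_id
        self.timer[idx] = best_t
        self.timer_rule[idx] = best_r

    def spawn(self, sp: int, act: int, pos: np.ndarray) -> int:
        self._grow(1)
        i = self.n
        self.n += 1
        self.species[i] = sp
        self.active[i] = bool(act)
        self.bound[i] = -1
        self.partner[i] = -1
        self.is_carrier[i] = False
        self.alive[i] = True
        self.pos[i] = _clip_radius(pos, sp, self.config.geometry)
        self.timer[i] = np.inf
        self.timer_rule[i] = -1
        self.births += 1
        self.rearm(i, keep_running=False)
        return i

    def kill(self, idx: int) -> None:
        self.alive[idx] = False
        self.timer[idx] = np.inf
        self.timer_rule[idx] = -1
        self.deaths += 1


@functools.lru_cache(maxsize=32)
def _shell_bounds(geometry: CompartmentGeometry) -> np.ndarray:
    """(2, n_species) radial [lo, hi] bounds per species."""
    out = np.zeros((2, _NS))
    for sp, (lo_name, hi_name) in SPECIES_SHELLS.items():
        i = _SP_CODE[sp]
        out[0, i] = 0.0 if lo_name is None else getattr(geometry, lo_name)
        out[1, i] = getattr(geometry, hi_name)
    return out


def _clip_radius(pos: np.ndarray, sp: int, geometry: CompartmentGeometry) -> np.ndarray:
    bounds = _shell_bounds(geometry)
    lo, hi = bounds[0, sp], bounds[1, sp]
    r = float(np.linalg.norm(pos))
    if lo <= r <= hi:
        return pos
    if r < 1e-12:
        return np.array([lo, 0.0, 0.0]) if lo > 0 else pos
    return pos * (min(max(r, lo), hi) / r)


_STATIC_CODES = frozenset(_SP_CODE[sp] for sp in STATIC_SPECIES)
_IS_STATIC = np.zeros(_NS, dtype=bool)
for _sp in STATIC_SPECIES:
    _IS_STATIC[_SP_CODE[_sp]] = True


def init_state(config: SimulationConfig) -> SimState:
    """Place the initial population uniformly inside each species' shell.

    All molecules start inactive and unbound; membrane species sit exactly
    on the cell surface.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    ruleset = compile_rules(config.rules)
    total = config.total_agents
    cap = max(16, int(total * 2))
    bounds = _shell_bounds(config.geometry)

    species = np.zeros(cap, dtype=np.int16)
    pos = np.zeros((cap, 3))
    i0 = 0
    for sp_name in SPECIES:
        count = int(config.initial_counts.get(sp_name, 0))
        if count == 0:
            continue
        sp = _SP_CODE[sp_name]
        lo, hi = bounds[0, sp], bounds[1, sp]
        direction = rng.standard_normal((count, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        if lo == hi:  # membrane shell
            r = np.full(count, hi)
        else:
            u = rng.uniform(size=count)
            r = (lo ** 3 + u * (hi ** 3 - lo ** 3)) ** (1.0 / 3.0)
        species[i0:i0 + count] = sp
        pos[i0:i0 + count] = direction * r[:, None]
        i0 += count

    state = SimState(
        config=config, time=0.0, rng=rng, ruleset=ruleset,
        pos=pos, species=species,
        active=np.zeros(cap, bool),
        bound=np.full(cap, -1, dtype=np.int16),
        partner=np.full(cap, -1, dtype=np.int64),
        is_carrier=np.zeros(cap, bool),
        alive=np.concatenate([np.ones(i0, bool), np.zeros(cap - i0, bool)]),
        timer=np.full(cap, np.inf),
        timer_rule=np.full(cap, -1, dtype=np.int16),
        n=i0,
        load=square_wave(0.0, config.stimulus),
    )
    for i in range(i0):
        state.rearm(i, keep_running=False)
    return state


# --------------------------------------------------------------------------
# per-step operators
# --------------------------------------------------------------------------

def apply_load(state: SimState, stim: MechanicalStimulus | None = None) -> SimState:
    """Switch membrane integrins on according to the current load.

    The per-step activation probability of an inactive integrin is linear
    in the load above baseline, ``k * (load - m0) / (M_ref - m0)``, so it
    vanishes exactly at the baseline and equals the configured
    ``activation_rate`` at the reference magnitude.
    """
    cfg = state.config
    stim = stim or cfg.stimulus
    state.load = square_wave(state.time, stim)
    p = cfg.activation_rate * (state.load - stim.baseline) / (
        cfg.reference_magnitude - stim.baseline)
    if p <= 0:
        return state
    n = state.n
    sel = (state.alive[:n] & (state.species[:n] == _SP_CODE["integrin"])
           & ~state.active[:n] & (state.bound[:n] == -1))
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return state
    fire = idx[state.rng.uniform(size=idx.size) < p]
    state.active[fire] = True
    for i in fire:
        state.rearm(int(i), keep_running=False)
    return state


def move_agents(state: SimState, config: SimulationConfig | None = None) -> SimState:
    """Isotropic Gaussian displacement with radial reflection at each
    species' shell walls; static membrane species and bound non-carrier
    agents do not self-move (complexes ride on their carrier)."""
    cfg = config or state.config
    step = cfg.diffusion_step
    n = state.n
    if n == 0:
        return state
    static = _IS_STATIC[state.species[:n]]
    mobile = state.alive[:n] & ~static & (
        (state.partner[:n] == -1) | state.is_carrier[:n])
    idx = np.flatnonzero(mobile)
    if step > 0 and idx.size:
        disp = state.rng.standard_normal((idx.size, 3)) * step
        newpos = state.pos[idx] + disp
        bounds = _shell_bounds(cfg.geometry)
        lo = bounds[0, state.species[idx]]
        hi = bounds[1, state.species[idx]]
        r = np.sqrt(np.einsum("ij,ij->i", newpos, newpos))
        for _ in range(3):
            over = r > hi
            r = np.where(over, 2 * hi - r, r)
            under = r < lo
            r = np.where(under, 2 * lo - r, r)
            if not (np.any(over) or np.any(under)):
                break
        r = np.clip(r, lo, hi)
        old_r = np.sqrt(np.einsum("ij,ij->i", newpos, newpos))
        scale = np.where(old_r > 1e-12, r / np.maximum(old_r, 1e-12), 1.0)
        state.pos[idx] = newpos * scale[:, None]
    # bound partners ride with the carrier
    carriers = np.flatnonzero(state.alive[:n] & state.is_carrier[:n])
    if carriers.size:
        state.pos[state.partner[carriers]] = state.pos[carriers]
    return state


def _nearest_within(seek_pos: np.ndarray, targ_pos: np.ndarray, radius: float,
                    method: str = "kdtree") -> np.ndarray:
    """Index of the nearest target within ``radius`` for each seeker
    (-1 when none).  ``method='brute'`` is the O(n^2) reference scan."""
    m = len(seek_pos)
    if len(targ_pos) == 0 or m == 0:
        return np.full(m, -1, dtype=np.int64)
    if method == "brute":
        from scipy.spatial.distance import cdist
        d = cdist(seek_pos, targ_pos)
        j = np.argmin(d, axis=1)
        out = np.where(d[np.arange(m), j] <= radius, j, -1)
        return out.astype(np.int64)
    tree = cKDTree(targ_pos)
    dist, j = tree.query(seek_pos, k=1, distance_upper_bound=radius)
    return np.where(np.isfinite(dist), j, -1).astype(np.int64)


def apply_bindings(state: SimState, rules: RuleSet | None = None,
                   rng: np.random.Generator | None = None,
                   method: str = "kdtree") -> SimState:
    """Nearest-partner binding within ``R_inter`` for every binding rule.

    Each agent takes part in at most one binding per step; conflicts are
    resolved in a seeded random permutation order (first claim wins, the
    loser skips this step rather than falling back to its second-nearest
    partner).
    """
    ruleset = rules or state.ruleset
    rng = rng or state.rng
    cfg = state.config
    n = state.n
    if n == 0 or not ruleset.bindings:
        return state
    rank = rng.permutation(n)
    used = np.zeros(n, bool)
    unbound = state.bound[:n] == -1
    for cb in ruleset.bindings:
        radius = cfg.r_inter if cb.range_limited else np.inf
        seek = np.flatnonzero(
            state.alive[:n] & ~used & unbound
            & (state.species[:n] == cb.seek[0])
            & (state.active[:n] == bool(cb.seek[1])))
        if seek.size == 0:
            continue
        targ = np.flatnonzero(
            state.alive[:n] & ~used & unbound
            & (state.species[:n] == cb.target[0])
            & (state.active[:n] == bool(cb.target[1])))
        if targ.size == 0:
            continue
        # process seekers in permutation order
        seek = seek[np.argsort(rank[seek], kind="stable")]
        j = _nearest_within(state.pos[seek], state.pos[targ], radius, method)
        ok = j >= 0
        seek, j = seek[ok], j[ok]
        if seek.size == 0:
            continue
        # first claim per target wins
        _, first = np.unique(j, return_index=True)
        first.sort()
        s_idx = seek[first]
        t_idx = targ[j[first]]
        used[s_idx] = True
        used[t_idx] = True
        _apply_binding_products(state, cb, s_idx, t_idx)
        unbound = state.bound[:n] == -1
    return state


def _apply_binding_products(state: SimState, cb: _CompiledBinding,
                            s_idx: np.ndarray, t_idx: np.ndarray) -> None:
    psa, paa, pba = cb.seek_product
    psb, pab, pbb = cb.target_product
    seek_changed = (psa, paa, pba) != (*cb.seek, -1)
    targ_changed = (psb, pab, pbb) != (*cb.target, -1)
    state.species[s_idx] = psa
    state.active[s_idx] = bool(paa)
    state.bound[s_idx] = pba
    state.species[t_idx] = psb
    state.active[t_idx] = bool(pab)
    state.bound[t_idx] = pbb
    if cb.forms_complex:
        state.partner[s_idx] = t_idx
        state.partner[t_idx] = s_idx
        state.is_carrier[s_idx] = cb.seeker_is_carrier
        state.is_carrier[t_idx] = not cb.seeker_is_carrier
        # the pair rides on the carrier's position
        if cb.seeker_is_carrier:
            state.pos[t_idx] = state.pos[s_idx]
        else:
            state.pos[s_idx] = state.pos[t_idx]
    for i in s_idx:
        if seek_changed or cb.forms_complex:
            state.rearm(int(i))
    for i in t_idx:
        if targ_changed or cb.forms_complex:
            state.rearm(int(i))


def fire_timers(state: SimState, rules: RuleSet | None = None) -> SimState:
    """Decrement all timers by dt and fire the rules of expired clocks.

    A personal clock expiring on a bound molecule performs a partial
    dissociation: only the state-changed molecule breaks away and its
    partner is released unchanged.
    """
    ruleset = rules or state.ruleset
    dt = state.config.dt
    n = state.n
    state.timer[:n] = state.timer[:n] - dt
    fired = np.flatnonzero(state.alive[:n] & (state.timer[:n] <= 1e-9)
                           & (state.timer_rule[:n] >= 0))
    if fired.size == 0:
        return state
    fired = fired[state.rng.permutation(fired.size)]
    rule_by_id = ruleset.by_id
    nucleus_r = state.config.geometry.nucleus_radius
    for i in fired:
        i = int(i)
        # a previously fired agent in this pass may have rearmed us
        if not state.alive[i] or state.timer_rule[i] < 0 or state.timer[i] > 1e-9:
            continue
        ct = rule_by_id[int(state.timer_rule[i])]
        if ct.kind == "state_transition":
            # a state change of a bound molecule breaks up the complex:
            # the changed molecule dissociates, the partner is released
            partner = int(state.partner[i])
            state.species[i], state.active[i] = ct.self_product[0], bool(
                ct.self_product[1])
            state.bound[i] = -1
            state.partner[i] = -1
            state.is_carrier[i] = False
            state.timer[i] = np.inf
            state.timer_rule[i] = -1
            state.pos[i] = _clip_radius(state.pos[i], int(state.species[i]),
                                        state.config.geometry)
            state.rearm(i)
            if partner >= 0:
                state.bound[partner] = -1
                state.partner[partner] = -1
                state.is_carrier[partner] = False
                state.timer[partner] = np.inf
                state.timer_rule[partner] = -1
                state.rearm(partner)
        elif ct.kind == "dissociation":
            partner = int(state.partner[i])
            state.species[i], state.active[i] = ct.self_product[0], bool(
                ct.self_product[1])
            state.bound[i] = -1
            state.partner[i] = -1
            state.is_carrier[i] = False
            state.timer[i] = np.inf
            state.timer_rule[i] = -1
            state.rearm(i)
            if partner >= 0:
                state.species[partner] = ct.partner_product[0]
                state.active[partner] = bool(ct.partner_product[1])
                state.bound[partner] = -1
                state.partner[partner] = -1
                state.is_carrier[partner] = False
                state.rearm(partner)
            for sp, act in ct.spawns:
                state.spawn(sp, act, state.pos[i].copy())
        elif ct.kind == "production":
            if ct.nucleus_gated and np.linalg.norm(state.pos[i]) >= nucleus_r:
                # not in the nucleus: postpone and redraw
                state.timer[i] = np.inf
                state.rearm(i, keep_running=False)
                continue
            for sp, act in ct.spawns:
                state.spawn(sp, act, state.pos[i].copy())
            state.timer[i] = np.inf
            state.rearm(i, keep_running=False)
        elif ct.kind == "degradation":
            partner = int(state.partner[i])
            if partner >= 0:
                state.bound[partner] = -1
                state.partner[partner] = -1
                state.is_carrier[partner] = False
                state.rearm(partner)
            state.kill(i)
    return state


# --------------------------------------------------------------------------
# recording
# --------------------------------------------------------------------------

def record_counts(state: SimState) -> np.ndarray:
    """One row of per-label counts over the full label universe.

    The compartment is derived from the agent's current radial position
    (membrane species always count as membrane).
    """
    n = state.n
    alive = state.alive[:n]
    sp = state.species[:n][alive].astype(np.int64)
    act = state.active[:n][alive].astype(np.int64)
    bnd = state.bound[:n][alive].astype(np.int64)
    p = state.pos[:n][alive]
    r = np.sqrt(np.einsum("ij,ij->i", p, p))
    geo = state.config.geometry
    comp = np.ones(sp.size, dtype=np.int64)  # cytoplasm
    comp[r < geo.nucleus_radius] = 0
    comp[r > geo.cell_radius] = 3
    comp[_IS_STATIC[sp]] = 2  # membrane
    codes = ((sp * 2 + act) * (_NS + 1) + (bnd + 1)) * _NCOMP + comp
    return np.bincount(codes, minlength=N_CODES).astype(np.int64)


@dataclass
class StateTimeSeries:
    """Per-step molecular counts partitioned by state label."""

    times: np.ndarray
    counts: np.ndarray                 # (n_times, n_labels) int
    labels: tuple[StateLabel, ...]
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.times.size, len(self.labels)):
            raise ValueError("counts shape does not match times/labels")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0

    def tokens(self) -> list[str]:
        return [lab.token for lab in self.labels]

    def column(self, selector: str | StateLabel) -> np.ndarray:
        """Counts for a label, or a pattern with ``any`` fields summed.

        ``selector`` may be an exact token (``MEK.inactive.RAF.cytoplasm``),
        a pattern token with ``any`` parts (``MEK.any.RAF.any``), or a
        :class:`StateLabel`.
        """
        if isinstance(selector, StateLabel):
            pattern = (selector.species, selector.activation,
                       selector.bound or "none", selector.compartment)
        else:
            parts = selector.split(".")
            if len(parts) != 4:
                raise KeyError(f"malformed label selector {selector!r}")
            pattern = tuple(parts)
        cols = [k for k, lab in enumerate(self.labels)
                if all(p in (q, ANY) or q == ANY for p, q in zip(
                    pattern, (lab.species, lab.activation,
                              lab.bound or "none", lab.compartment)))]
        if not cols:
            raise KeyError(
                f"no label matches {selector!r}; available: "
                f"{', '.join(self.tokens())}")
        return self.counts[:, cols].sum(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=pd.Index(self.times, name="time_s"),
                            columns=self.tokens())


def run_simulation(config: SimulationConfig,
                   progress: bool = False) -> StateTimeSeries:
    """Run the agent model and return the recorded count series.

    Per-step order: load coupling, Brownian motion, nearest-partner
    bindings, timer expiry, recording.  The returned series has
    ``duration/dt + 1`` rows (the initial condition plus one per step).
    """
    state = init_state(config)
    n_steps = config.n_steps
    rows = np.zeros((n_steps + 1, N_CODES), dtype=np.int32)
    rows[0] = record_counts(state)
    for k in range(1, n_steps + 1):
        state.time = (k - 1) * config.dt  # load evaluated at step start
        apply_load(state)
        move_agents(state)
        apply_bindings(state)
        fire_timers(state)
        state.time = k * config.dt
        rows[k] = record_counts(state)
    keep = np.flatnonzero(rows.any(axis=0))
    labels = tuple(code_to_label(int(c)) for c in keep)
    times = np.arange(n_steps + 1) * config.dt
    return StateTimeSeries(times=times, counts=rows[:, keep], labels=labels,
                           config_hash=config_hash(config))
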