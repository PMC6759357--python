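"""Design of zwuis multitone stimuli with unambiguous distortion products.

A zwuis complex is a set of tones whose frequencies are distinct integer
multiples ``n_k`` of one base frequency (the reciprocal of the coherent
analysis window).  The multiples are chosen such that every second-order
intermodulation product ``n_k ± n_m`` has a unique frequency, distinct from
all primaries, and such that third-order products never fall on a primary.
Under these conditions each second-order distortion product (DP2) in a
recorded response can be attributed to exactly one pair of parent primaries.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ZwuisStimulus",
    "DesignConstraints",
    "UniquenessCertificate",
    "DesignError",
    "enumerate_dp_frequencies",
    "validate_uniqueness",
    "design_zwuis",
    "synthesize_waveform",
    "sound_pressure_pa",
]

#: dB SPL level of a 1-Pa-RMS tone (re 20 uPa).
DB_SPL_1PA = 20.0 * math.log10(1.0 / 20e-6)

DEFAULT_SAMPLE_RATE_HZ = 111600.0


class DesignError(RuntimeError):
    """Raised when no uniqueness-passing stimulus can be constructed."""


@dataclass
class ZwuisStimulus:
    """A zwuis multitone stimulus specification.

    Component frequencies are ``multipliers * base_frequency_hz``; levels are
    per-component dB SPL (re 20 uPa) and phases are starting phases in cycles,
    cosine convention.
    """

    base_frequency_hz: float
    multipliers: list[int]
    levels_db_spl: list[float]
    phases_cycles: list[float]
    duration_s: float = 12.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        m = list(self.multipliers)
        if len(m) != len(set(m)):
            raise ValueError("multipliers must be distinct")
        if any(x <= 0 for x in m):
            raise ValueError("multipliers must be positive")
        if m != sorted(m):
            raise ValueError("multipliers must be strictly increasing")
        if self.base_frequency_hz <= 0:
            raise ValueError("base frequency must be positive")
        nyq = self.sample_rate_hz / 2.0
        if max(m) * self.base_frequency_hz >= nyq:
            raise ValueError("component frequency at or above Nyquist")
        if not (len(m) == len(self.levels_db_spl) == len(self.phases_cycles)):
            raise ValueError("per-component field lengths differ")

    @property
    def n_components(self) -> int:
        return len(self.multipliers)

    @property
    def component_frequencies_hz(self) -> np.ndarray:
        return np.asarray(self.multipliers, dtype=float) * self.base_frequency_hz

    def replace_levels(self, levels_db_spl) -> "ZwuisStimulus":
        return ZwuisStimulus(
            self.base_frequency_hz,
            list(self.multipliers),
            [float(x) for x in levels_db_spl],
            list(self.phases_cycles),
            self.duration_s,
            self.sample_rate_hz,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ZwuisStimulus":
        return cls(**json.loads(text))


@dataclass
class DesignConstraints:
    """Constraints for the randomized zwuis search.

    ``cf_hz``/``cf_fraction_limit`` implement the CF/2 rule: primaries (and
    hence the analyzed DP2s used downstream) stay at or below half the
    characteristic frequency of the recording site, where travelling-wave
    interference is negligible.
    """

    n_components: int
    f_min_hz: float = 300.0
    f_max_hz: float = 1e9
    cf_hz: float | None = None
    cf_fraction_limit: float = 0.5
    max_order_unambiguous: int = 3
    strict: bool = False
    seed: int = 0
    max_search_iterations: int = 500_000
    base_frequency_hz: float = 1.0
    duration_s: float = 12.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    level_db_spl: float = 60.0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("need at least 2 components")
        if not self.f_min_hz < self.f_max_hz:
            raise ValueError("f_min_hz must be below f_max_hz")
        if not 0.0 < self.cf_fraction_limit <= 1.0:
            raise ValueError("cf_fraction_limit must lie in (0, 1]")
        if self.max_order_unambiguous not in (2, 3):
            raise ValueError("max_order_unambiguous must be 2 or 3")


@dataclass
class UniquenessCertificate:
    passed: bool
    collisions: list[tuple] = field(default_factory=list)
    n_dp2: int = 0
    n_dp3: int = 0
    mode: str = "default"

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def enumerate_dp_frequencies(multipliers, order: int) -> dict:
    """Map combination signatures to integer DP frequency multiples.

    Order 2 signatures are ``(k, m, sign)`` with component indices ``k >= m``:
    sums ``n_k + n_m`` (including second harmonics ``2 n_k`` for ``k == m``)
    and differences ``n_k - n_m`` for ``k > m``.  Order 3 signatures are
    canonical coefficient tuples ``((index, coeff), ...)`` with
    ``sum(|coeff|) == 3``; a repeated index carries a single signed
    coefficient (mixed signs on one index reduce to lower order), the overall
    sign is chosen to make the combination positive, and zero-valued
    combinations are dropped.
    """
    m = list(multipliers)
    if len(m) != len(set(m)):
        raise ValueError("multipliers must be distinct")
    if order == 2:
        out: dict = {}
        for k in range(len(m)):
            for j in range(k + 1):
                out[(k, j, "+")] = m[k] + m[j]
                if j < k:
                    out[(k, j, "-")] = m[k] - m[j]
        return out
    if order == 3:
        out = {}
        for idx in itertools.combinations_with_replacement(range(len(m)), 3):
            for signs in itertools.product((1, -1), repeat=3):
                coeff: dict[int, int] = {}
                ok = True
                for i, s in zip(idx, signs):
                    if i in coeff and (coeff[i] > 0) != (s > 0):
                        ok = False
                        break
                    coeff[i] = coeff.get(i, 0) + s
                if not ok:
                    continue
                val = sum(c * m[i] for i, c in coeff.items())
                if val == 0:
                    continue
                if val < 0:
                    coeff = {i: -c for i, c in coeff.items()}
                    val = -val
                key = tuple(sorted(coeff.items()))
                out[key] = val
        return out
    raise ValueError("order must be 2 or 3")


def validate_uniqueness(
    multipliers,
    constraints: DesignConstraints | None = None,
    *,
    strict: bool | None = None,
    max_order: int | None = None,
) -> UniquenessCertificate:
    """Check that DP frequencies are uniquely attributable.

    Default rule: all order-2 multiples mutually distinct and distinct from
    every primary; all order-3 multiples distinct from every primary.  In
    strict mode the order-3 multiples must additionally be mutually distinct
    and disjoint from the order-2 set.  Collisions are reported as
    ``(value, signature_a, signature_b)`` where signatures of bare primaries
    are ``("primary", index)``.
    """
    m = list(multipliers)
    if len(m) < 2:
        return UniquenessCertificate(True, [], 0, 0, "vacuous")
    if strict is None:
        strict = constraints.strict if constraints is not None else False
    if max_order is None:
        max_order = (
            constraints.max_order_unambiguous if constraints is not None else 3
        )

    prim = {v: ("primary", i) for i, v in enumerate(m)}
    collisions: list[tuple] = []

    dp2 = enumerate_dp_frequencies(m, 2)
    seen: dict[int, tuple] = {}
    for sig, val in dp2.items():
        if val in seen:
            collisions.append((val, seen[val], sig))
        else:
            seen[val] = sig
        if val in prim:
            collisions.append((val, prim[val], sig))

    dp3 = {}
    if max_order >= 3:
        dp3 = enumerate_dp_frequencies(m, 3)
        seen3: dict[int, tuple] = {}
        for sig, val in dp3.items():
            if val in prim:
                collisions.append((val, prim[val], sig))
            if strict:
                if val in seen3:
                    collisions.append((val, seen3[val], sig))
                else:
                    seen3[val] = sig
                if val in seen:
                    collisions.append((val, seen[val], sig))

    mode = "strict" if strict else "default"
    return UniquenessCertificate(not collisions, collisions, len(dp2), len(dp3), mode)


def _new_dp2_values(n: int, existing: list[int]) -> list[int]:
    vals = [2 * n]
    for q in existing:
        vals.append(n + q)
        vals.append(abs(n - q))
    return vals


def _new_dp3_values(n: int, existing: list[int]) -> list[int]:
    vals = [3 * n]
    for q in existing:
        vals.extend((2 * n + q, abs(2 * n - q), n + 2 * q, abs(n - 2 * q)))
    for i in range(len(existing)):
        a = existing[i]
        for j in range(i + 1, len(existing)):
            b = existing[j]
            vals.extend(
                (n + a + b, abs(n + a - b), abs(n - a + b), abs(n - a - b))
            )
    return [v for v in vals if v > 0]


def _candidate_ok(n, chosen, prim_set, dp2_set, dp3_set, strict, max_order):
    if n in prim_set or n in dp2_set or n in dp3_set:
        return None
    new2 = _new_dp2_values(n, chosen)
    s2 = set(new2)
    if len(s2) != len(new2):
        return None
    if s2 & dp2_set or s2 & prim_set or n in s2:
        return None
    new3: list[int] = []
    if max_order >= 3:
        new3 = _new_dp3_values(n, chosen)
        s3 = set(new3)
        if s3 & prim_set or n in s3:
            return None
        if strict:
            if len(s3) != len(new3):
                return None
            if s3 & dp3_set or s3 & dp2_set or s3 & s2 or s2 & dp3_set:
                return None
    return new2, new3


def design_zwuis(constraints: DesignConstraints) -> ZwuisStimulus:
    """Search for a uniqueness-passing zwuis stimulus.

    Multipliers are drawn by seeded jittered-stratified sampling (one integer
    per equal-width stratum of the admissible band) with depth-first
    backtracking: each accepted component must keep the incremental DP
    catalog collision-free.  Component levels start equal; starting phases
    are randomized uniformly from the same seeded generator.
    """
    c = constraints
    base = c.base_frequency_hz
    nyq = c.sample_rate_hz / 2.0
    f_hi = min(c.f_max_hz, nyq * (1 - 1e-9))
    limit_name = "f_max_hz" if c.f_max_hz <= nyq else "Nyquist"
    if c.cf_hz is not None and c.cf_fraction_limit * c.cf_hz < f_hi:
        f_hi = c.cf_fraction_limit * c.cf_hz
        limit_name = "cf_fraction_limit * cf_hz"
    lo = int(math.ceil(c.f_min_hz / base))
    hi = int(math.floor(f_hi / base))
    n = c.n_components
    if hi - lo + 1 < n:
        raise DesignError(
            f"infeasible band: {hi - lo + 1} integer slots between "
            f"f_min_hz={c.f_min_hz} and {limit_name}={f_hi} at base "
            f"{base} Hz for {n} components"
        )
    if abs(c.duration_s * base - round(c.duration_s * base)) > 1e-9:
        raise DesignError("duration_s must be an integer number of base periods")

    edges = np.linspace(lo, hi + 1, n + 1)
    evals = 0
    for attempt in range(32):
        rng = np.random.default_rng((c.seed, attempt))
        pools = []
        for s in range(n):
            a, b = int(math.ceil(edges[s])), int(math.ceil(edges[s + 1]))
            pool = np.arange(a, b)
            rng.shuffle(pool)
            pools.append(pool)
        chosen: list[int] = []
        undo: list[tuple] = []
        prim_set: set[int] = set()
        dp2_set: set[int] = set()
        dp3_set: set[int] = set()
        pos = [0] * n
        depth = 0
        while 0 <= depth < n:
            if evals > c.max_search_iterations:
                raise DesignError(
                    "search budget exhausted; tightest constraint is the "
                    f"uniqueness rule ({'strict' if c.strict else 'default'}) "
                    f"with {n} components in [{c.f_min_hz}, {f_hi}] Hz "
                    f"(limited by {limit_name})"
                )
            pool = pools[depth]
            found = False
            while pos[depth] < len(pool):
                cand = int(pool[pos[depth]])
                pos[depth] += 1
                evals += 1
                res = _candidate_ok(
                    cand, chosen, prim_set, dp2_set, dp3_set,
                    c.strict, c.max_order_unambiguous,
                )
                if res is not None:
                    new2, new3 = res
                    chosen.append(cand)
                    prim_set.add(cand)
                    dp2_set.update(new2)
                    dp3_set.update(new3)
                    undo.append((cand, new2, new3))
                    depth += 1
                    found = True
                    break
            if not found:
                pos[depth] = 0
                rng.shuffle(pools[depth])
                depth -= 1
                if depth >= 0 and chosen:
                    cand, new2, new3 = undo.pop()
                    chosen.pop()
                    prim_set.discard(cand)
                    dp2_set.difference_update(new2)
                    dp3_set.difference_update(new3)
        if depth == n:
            multipliers = sorted(chosen)
            cert = validate_uniqueness(multipliers, c)
            assert cert.passed, "internal search/validator disagreement"
            phases = rng.uniform(0.0, 1.0, size=n)
            return ZwuisStimulus(
                base_frequency_hz=base,
                multipliers=multipliers,
                levels_db_spl=[c.level_db_spl] * n,
                phases_cycles=[float(p) for p in phases],
                duration_s=c.duration_s,
                sample_rate_hz=c.sample_rate_hz,
            )
    raise DesignError(
        f"no uniqueness-passing set found after {evals} candidate "
        f"evaluations; tightest constraint: {limit_name}"
    )


def synthesize_waveform(
    stimulus: ZwuisStimulus, reference_db_spl: float = 0.0
) -> np.ndarray:
    """Additively synthesize the stimulus waveform.

    Each component contributes ``10**((level - reference_db_spl)/20) *
    cos(2 pi f t + 2 pi phase)``, i.e. the output is in units in which a
    component at the reference level has unit peak amplitude.  The duration
    must be coherent (an integer number of base periods) so every component
    completes an integer number of cycles.
    """
    cyc = stimulus.duration_s * stimulus.base_frequency_hz
    if abs(cyc - round(cyc)) > 1e-9:
        raise ValueError("non-coherent duration: not an integer number of base periods")
    n = int(round(stimulus.duration_s * stimulus.sample_rate_hz))
    t = np.arange(n) / stimulus.sample_rate_hz
    x = np.zeros(n)
    freqs = stimulus.component_frequencies_hz
    for f, lev, ph in zip(freqs, stimulus.levels_db_spl, stimulus.phases_cycles):
        a = 10.0 ** ((lev - reference_db_spl) / 20.0)
        x += a * np.cos(2 * np.pi * (f * t + ph))
    return x


def sound_pressure_pa(stimulus: ZwuisStimulus) -> np.ndarray:
    """Stimulus pressure waveform in Pa (levels read as dB SPL re 20 uPa RMS)."""
    # peak amplitude of an L-dB-SPL tone is sqrt(2) * 20e-6 * 10**(L/20) Pa
    return math.sqrt(2.0) * synthesize_waveform(stimulus, reference_db_spl=DB_SPL_1PA)
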