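"""Monte-Carlo type-I error and power experiments.

Samples correlated z-score vectors X ~ MVN(mu, Sigma), converts each
coordinate into left-sided (Phi(X_i)), right-sided (1 - Phi(X_i)) and
two-sided (2 Phi(-|X_i|)) p-values, applies the combination tests per
replicate, and reports empirical rejection proportions, their ratio to
the nominal significance level, and binomial Monte-Carlo standard errors.

A ratio of 1 means exact calibration under the global null; below 1,
conservatism.  Replicates are processed in fixed-size chunks with one RNG
substream per chunk, so runs are reproducible for a given seed and chunk
size and memory stays bounded at large k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .combine import P_ONE_CLIP, _cauchy_sf, _cct_stat_rows, _minp_rows
from .correlation import CorrelationSpec, factorize_for_sampling

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "RejectionTable",
    "sample_mvn",
    "three_sided_pvalues",
    "estimate_rejection_rates",
    "run_grid",
    "table1_configs",
]

_TESTS = ("CCT", "MinP", "MCM", "CMC")
_SIDES = ("left", "right", "two")
_PLACEMENTS = ("head", "spread", "random")

#: replicates per chunk; fixed so that results depend only on the seed.
DEFAULT_CHUNK = 100_000


@dataclass(frozen=True)
class EffectSpec:
    """Mean shift of the z-score vector under the alternative.

    ``n_significant`` coordinates get mean +/- ``mu``; of those, the
    first ``n_negative`` get -mu and the rest +mu.  ``placement``
    controls which coordinates are shifted: the leading block (``head``),
    evenly spaced (``spread``), or a seeded random subset (``random``) --
    it matters under structured correlation.  ``mu = 0`` (with
    ``n_significant = 0``) is the global null.
    """

    n_significant: int = 0
    n_negative: int = 0
    mu: float = 0.0
    placement: str = "head"

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0 <= self.n_negative <= self.n_significant:
            raise ValueError("need 0 <= n_negative <= n_significant")
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"placement must be one of {_PLACEMENTS}")
        if self.mu == 0.0 and self.n_significant > 0:
            raise ValueError("mu = 0 must go with n_significant = 0 (null configuration)")

    def mean_vector(self, k: int, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.n_significant > k:
            raise ValueError(f"n_significant={self.n_significant} exceeds k={k}")
        mean = np.zeros(k)
        if self.n_significant == 0:
            return mean
        if self.placement == "head":
            idx = np.arange(self.n_significant)
        elif self.placement == "spread":
            idx = np.unique(np.linspace(0, k - 1, self.n_significant).round().astype(int))
        else:
            if rng is None:
                raise ValueError("placement='random' requires a generator")
            idx = rng.choice(k, size=self.n_significant, replace=False)
            idx.sort()
        mean[idx[: self.n_negative]] = -self.mu
        mean[idx[self.n_negative :]] = self.mu
        return mean


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one Monte-Carlo experiment."""

    spec: CorrelationSpec
    effect: EffectSpec = EffectSpec()
    n_replicates: int = 1_000_000
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001)
    seed: int = 0
    tests: tuple[str, ...] = _TESTS
    sides: tuple[str, ...] = ("left",)
    minp_mode: str = "sidak"
    chunk_size: int = DEFAULT_CHUNK

    def __post_init__(self):
        object.__setattr__(self, "alphas", tuple(sorted(self.alphas, reverse=True)))
        object.__setattr__(self, "tests", tuple(self.tests))
        object.__setattr__(self, "sides", tuple(self.sides))
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.alphas or any(not 0 < a < 0.5 for a in self.alphas):
            raise ValueError("alphas must be a non-empty list of levels in (0, 0.5)")
        if not self.tests:
            raise ValueError("tests must be a non-empty subset of " + str(_TESTS))
        bad = [t for t in self.tests if t not in _TESTS]
        if bad:
            raise ValueError(f"unknown tests {bad}; expected a subset of {_TESTS}")
        bad = [s for s in self.sides if s not in _SIDES]
        if bad or not self.sides:
            raise ValueError(f"sides must be a non-empty subset of {_SIDES}")
        if self.minp_mode not in ("sidak", "bonferroni"):
            raise ValueError("minp_mode must be 'sidak' or 'bonferroni'")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "effect": {
                "n_significant": self.effect.n_significant,
                "n_negative": self.effect.n_negative,
                "mu": self.effect.mu,
                "placement": self.effect.placement,
            },
            "n_replicates": self.n_replicates,
            "alphas": list(self.alphas),
            "seed": self.seed,
            "tests": list(self.tests),
            "sides": list(self.sides),
            "minp_mode": self.minp_mode,
            "chunk_size": self.chunk_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        problems = []
        if "spec" not in d:
            problems.append("missing 'spec' section")
        extra = set(d) - {
            "spec", "effect", "n_replicates", "alphas", "seed", "tests",
            "sides", "minp_mode", "chunk_size",
        }
        if extra:
            problems.append(f"unknown keys {sorted(extra)}")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))
        eff = d.get("effect", {})
        return cls(
            spec=CorrelationSpec.from_dict(d["spec"]),
            effect=EffectSpec(
                n_significant=int(eff.get("n_significant", 0)),
                n_negative=int(eff.get("n_negative", 0)),
                mu=float(eff.get("mu", 0.0)),
                placement=eff.get("placement", "head"),
            ),
            n_replicates=int(d.get("n_replicates", 1_000_000)),
            alphas=tuple(d.get("alphas", (0.05, 0.01, 0.001, 0.0001))),
            seed=int(d.get("seed", 0)),
            tests=tuple(d.get("tests", _TESTS)),
            sides=tuple(d.get("sides", ("left",))),
            minp_mode=d.get("minp_mode", "sidak"),
            chunk_size=int(d.get("chunk_size", DEFAULT_CHUNK)),
        )


@dataclass
class RejectionTable:
    """Empirical rejection rates for one configuration.

    ``table`` has one row per (test, side, alpha) with columns
    ``rate`` (rejection proportion), ``ratio`` (rate / alpha) and ``se``
    (binomial standard error of the rate).
    """

    config: SimulationConfig
    table: pd.DataFrame = field(repr=False)

    def ratio(self, test: str, side: str, alpha: float) -> float:
        t = self.table
        row = t[(t.test == test) & (t.side == side) & np.isclose(t.alpha, alpha)]
        if row.empty:
            raise KeyError(f"no cell for ({test}, {side}, {alpha})")
        return float(row.ratio.iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "model", self.config.spec.model)
        out.insert(1, "k", self.config.spec.k)
        out.insert(2, "parameter", self.config.spec.parameter)
        return out


def _chunk_rngs(seed: int, n: int, chunk: int):
    """Yield (chunk_length, Generator) with one spawned substream per chunk."""
    ss = np.random.SeedSequence(seed)
    n_chunks = (n + chunk - 1) // chunk
    children = ss.spawn(n_chunks)
    start = 0
    for child in children:
        m = min(chunk, n - start)
        start += m
        yield m, np.random.default_rng(child)


def sample_mvn(
    spec: CorrelationSpec,
    effect: EffectSpec,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw n i.i.d. rows from MVN(mean, Sigma) for the given model.

    The mean vector comes from ``effect.mean_vector``; seeded runs are
    bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = factorize_for_sampling(spec.matrix())
    mean = effect.mean_vector(spec.k, rng=rng)
    return mean + rng.standard_normal((n, spec.k)) @ B


def three_sided_pvalues(z) -> dict[str, np.ndarray]:
    """Left, right, and two-sided p-values for an array of z-scores.

    left = Phi(z), right = 1 - Phi(z), two = 2 Phi(-|z|).  The smaller
    tail is evaluated directly and its complement as 1 minus it, so each
    (left, right) pair sums to 1 exactly in floating point.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    small = ndtr(-np.abs(z))
    large = 1.0 - small
    left = np.where(z <= 0, small, large)
    right = np.where(z <= 0, large, small)
    return {"left": left, "right": right, "two": np.minimum(1.0, 2.0 * small)}


def _combined_pvalues_rows(P: np.ndarray, tests, minp_mode: str) -> dict[str, np.ndarray]:
    """Per-replicate combined p-values for a (replicates x k) p-value block."""
    k = P.shape[1]
    need_cct = {"CCT", "MCM", "CMC"} & set(tests)
    need_minp = {"MinP", "MCM", "CMC"} & set(tests)
    out = {}
    p_cct = _cauchy_sf(_cct_stat_rows(P)) if need_cct else None
    p_minp = _minp_rows(P.min(axis=1), k, minp_mode) if need_minp else None
    if "CCT" in tests:
        out["CCT"] = p_cct
    if "MinP" in tests:
        out["MinP"] = p_minp
    if "MCM" in tests:
        out["MCM"] = np.minimum(1.0, 2.0 * np.minimum(np.minimum(p_cct, p_minp), 0.5))
    if "CMC" in tests:
        pair = np.stack([p_cct, np.minimum(p_minp, P_ONE_CLIP)], axis=1)
        out["CMC"] = _cauchy_sf(_cct_stat_rows(pair))
    return out


def estimate_rejection_rates(config: SimulationConfig) -> RejectionTable:
    """Run one Monte-Carlo experiment and tabulate rejection rates.

    For each replicate, each selected test is applied to each selected
    p-value side; a replicate counts as rejected at level alpha when the
    combined p-value is <= alpha.  Replicates are processed in chunks of
    ``config.chunk_size`` with one RNG substream per chunk.
    """
    spec, effect = config.spec, config.effect
    B = factorize_for_sampling(spec.matrix())
    alphas = np.asarray(config.alphas)
    counts = {(t, s): np.zeros(alphas.size, dtype=np.int64)
              for t in config.tests for s in config.sides}
    mean = None
    for m, rng in _chunk_rngs(config.seed, config.n_replicates, config.chunk_size):
        if mean is None or effect.placement == "random":
            mean = effect.mean_vector(spec.k, rng=rng)
        X = mean + rng.standard_normal((m, spec.k)) @ B
        pmats = three_sided_pvalues(X)
        for side in config.sides:
            P = np.maximum(pmats[side], 1e-300)  # guard exact-zero tails
            combined = _combined_pvalues_rows(P, config.tests, config.minp_mode)
            for t in config.tests:
                counts[(t, side)] += (combined[t][:, None] <= alphas[None, :]).sum(axis=0)
    n = config.n_replicates
    rows = []
    for (t, s), c in counts.items():
        rate = c / n
        rows.append(pd.DataFrame({
            "test": t, "side": s, "alpha": alphas,
            "rate": rate, "ratio": rate / alphas,
            "se": np.sqrt(rate * (1.0 - rate) / n),
        }))
    table = pd.concat(rows, ignore_index=True)
    return RejectionTable(config=config, table=table)


def run_grid(configs, out_csv=None) -> pd.DataFrame:
    """Run a list of configurations; one tidy row per (model, k, parameter,
    test, side, alpha).  Deterministic given the configs' seeds."""
    configs = list(configs)
    if not configs:
        raise ValueError("run_grid needs at least one configuration")
    frames = []
    for cfg in configs:
        try:
            frames.append(estimate_rejection_rates(cfg).to_frame())
        except Exception as exc:
            raise RuntimeError(
                f"configuration failed: model={cfg.spec.model} k={cfg.spec.k} "
                f"parameter={cfg.spec.parameter} seed={cfg.seed}"
            ) from exc
    out = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def table1_configs(
    n_replicates: int = 1_000_000,
    seed: int = 0,
    ks=(5, 10, 20, 100),
    minp_mode: str = "sidak",
) -> list[SimulationConfig]:
    """The null grid behind the type-I error table: three correlation
    models (expo rho=0.5, poly r=1.5, sig d=0.5), four matrix sizes, four
    significance levels, left-sided p-values, all four tests."""
    params = {"expo": 0.5, "poly": 1.5, "sig": 0.5}
    configs = []
    for i, (model, par) in enumerate(params.items()):
        for j, k in enumerate(ks):
            configs.append(SimulationConfig(
                spec=CorrelationSpec(model=model, k=k, parameter=par),
                n_replicates=n_replicates,
                seed=seed + 97 * i + 11 * j,
                minp_mode=minp_mode,
            ))
    return configs


def power_config(config: SimulationConfig, n_significant: int, n_negative: int, mu: float,
                 placement: str = "head") -> SimulationConfig:
    """Derive a power configuration from a null one by adding a mean shift."""
    return replace(
        config,
        effect=EffectSpec(n_significant=n_significant, n_negative=n_negative,
                          mu=mu, placement=placement),
    )
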