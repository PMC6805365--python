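"""Synthetic two-group screening cohort generator.

Emulates a population-based cohort in which a low-back-pain (LBP) group and
a reference group answer two screening instruments (the 9-item STarT Back
tool and an 18-region pain mannequin) plus a battery of patient-reported
outcomes.  The generator is parameterized by group-level summary statistics
— PRO means/SDs, chronic-widespread-pain prevalence, percent women,
region-count marginal mean — so that simulation recovers the configured
values in expectation, which is what makes the downstream tables testable
without the study's (non-public) data.

Structure: one standard-normal latent severity per individual drives, via
a single coupling coefficient, (i) the probability of chronic pain, (ii)
the painful-region count (Gaussian copula into a zero-truncated negative
binomial, capped at 18), (iii) SBT item endorsement (logistic), and (iv)
the PRO values (moment-matched censored-normal marginals, EQ-5D coupled
inversely).  Conditional on severity the instruments are independent.
Widespreadness is decided given the region count with a probability
proportional to the exact combinatorial chance that a random set of that
size satisfies the ACR criterion, calibrated (one-dimensional root solve)
so the configured CWP prevalence is honored; the marked set is then
constructed to match both the count and the widespread/regional decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import expit
from scipy.stats import nbinom, norm

from .cohort import Cohort, IndividualRecord, PRO_FIELDS, PRO_RANGES
from .mannequin import BodyRegionMap, default_region_map, is_widespread
from .marginals import ScaleMarginal, solve_censored_normal
from .stats import scored_frame

__all__ = ["GroupConfig", "GeneratorConfig", "generate_cohort", "recover_parameters"]

AGE_RANGE = (40.0, 71.0)

#: rounding step of each PRO as administered
PRO_GRANULARITY = {name: 1.0 for name in PRO_FIELDS} | {"eq5d_index": 0.001}
#: EQ-5D is scored best-high, so it couples inversely to severity
PRO_SIGN = {name: 1 for name in PRO_FIELDS} | {"eq5d_index": -1}

MAX_REGIONS = 18


@dataclass(frozen=True)
class GroupConfig:
    """Summary-level generating parameters for one group."""

    n: int
    p_women: float
    age_mean: float
    age_sd: float
    p_chronic: float
    p_lower_back: float  # P(lower back marked | chronic)
    p_cwp: float  # marginal CWP prevalence in the group
    region_mean: float  # marginal mean painful-region count (0-18)
    region_dispersion: float  # NB size of the chronic count distribution
    sbt_item_probs: tuple[float, ...]  # marginal endorsement of the 9 items
    pro_means: dict[str, float] = field(default_factory=dict)
    pro_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        for name, p in [
            ("p_women", self.p_women),
            ("p_chronic", self.p_chronic),
            ("p_lower_back", self.p_lower_back),
            ("p_cwp", self.p_cwp),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_cwp > self.p_chronic:
            raise ValueError("CWP prevalence cannot exceed chronic-pain prevalence")
        if len(self.sbt_item_probs) != 9:
            raise ValueError("need 9 SBT item probabilities")
        if any(not (0.0 <= p <= 1.0) for p in self.sbt_item_probs):
            raise ValueError("SBT item probabilities outside [0, 1]")
        for name in self.pro_means:
            lo, hi = PRO_RANGES[name]
            if not (lo <= self.pro_means[name] <= hi):
                raise ValueError(f"{name} mean outside instrument range")


@dataclass(frozen=True)
class GeneratorConfig:
    lbp: GroupConfig
    reference: GroupConfig
    n_unassigned: int = 7
    coupling: float = 0.6
    sbt_missing: float = 0.0
    mannequin_missing: float = 0.0
    pro_missing: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling < 1.0):
            raise ValueError("coupling must lie in [0, 1)")
        for name in ("sbt_missing", "mannequin_missing", "pro_missing"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        groups = doc["groups"]

        def group(d: dict) -> GroupConfig:
            return GroupConfig(
                n=int(d["n"]),
                p_women=float(d["p_women"]),
                age_mean=float(d["age_mean"]),
                age_sd=float(d["age_sd"]),
                p_chronic=float(d["p_chronic"]),
                p_lower_back=float(d["p_lower_back"]),
                p_cwp=float(d["p_cwp"]),
                region_mean=float(d["region_mean"]),
                region_dispersion=float(d["region_dispersion"]),
                sbt_item_probs=tuple(float(p) for p in d["sbt_item_probs"]),
                pro_means={k: float(v) for k, v in d["pro_means"].items()},
                pro_sds={k: float(v) for k, v in d["pro_sds"].items()},
            )

        return cls(
            lbp=group(groups["lbp"]),
            reference=group(groups["reference"]),
            n_unassigned=int(doc.get("n_unassigned", 0)),
            coupling=float(doc.get("coupling", 0.6)),
            sbt_missing=float(doc.get("sbt_missing", 0.0)),
            mannequin_missing=float(doc.get("mannequin_missing", 0.0)),
            pro_missing=float(doc.get("pro_missing", 0.0)),
            seed=doc.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "GeneratorConfig":
        text = (
            resources.files("lbptriage")
            .joinpath("data/generator.yaml")
            .read_text("utf-8")
        )
        return cls.from_dict(yaml.safe_load(text))


# --- combinatorics of the widespread criterion --------------------------


def _categories(region_map: BodyRegionMap) -> dict[str, frozenset[str]]:
    return {
        "axial": frozenset(r.id for r in region_map.regions if r.axial),
        "left": frozenset(r.id for r in region_map.regions if r.side == "left"),
        "right": frozenset(r.id for r in region_map.regions if r.side == "right"),
        "upper": frozenset(r.id for r in region_map.regions if r.body_half == "upper"),
        "lower": frozenset(r.id for r in region_map.regions if r.body_half == "lower"),
    }


def widespread_probability(
    k: int, region_map: BodyRegionMap, forced: frozenset[str] = frozenset()
) -> float:
    """Exact P(uniform k-subset containing ``forced`` is ACR-widespread).

    Inclusion-exclusion over the unmet attribute requirements (axial, left,
    right, upper, lower): the probability that a uniform draw of the
    remaining regions leaves some requirement empty.
    """
    all_ids = frozenset(region_map.ids)
    if not forced <= all_ids:
        raise ValueError("forced regions not in map")
    if not (len(forced) <= k <= len(all_ids)):
        return 0.0
    forced_regions = [region_map[r] for r in forced]
    cats = _categories(region_map)
    unmet = [c for c in cats.values() if not any(r.id in c for r in forced_regions)]
    pool = all_ids - forced
    n, draw = len(pool), k - len(forced)
    total = math.comb(n, draw)
    prob_not = 0.0
    for mask in range(1, 1 << len(unmet)):
        union: set[str] = set()
        bits = 0
        for i, cat in enumerate(unmet):
            if mask >> i & 1:
                union |= cat & pool
                bits += 1
        avail = n - len(union)
        term = math.comb(avail, draw) / total if draw <= avail else 0.0
        prob_not += (-1) ** (bits + 1) * term
    return 1.0 - prob_not


# --- calibrated component laws (cached across generator calls) ----------


@lru_cache(maxsize=None)
def _ztnb_capped_pmf(
    target_mean: float, dispersion: float, cap: int = MAX_REGIONS
) -> tuple[float, ...]:
    """Pmf on 1..cap of a zero-truncated NB whose capped mean hits the target."""
    if not (1.0 < target_mean < cap):
        raise ValueError(f"conditional region-count mean {target_mean} out of (1, {cap})")
    ks = np.arange(1, cap + 1)

    def pmf_for(mu: float) -> np.ndarray:
        p = dispersion / (dispersion + mu)
        raw = nbinom.pmf(ks, dispersion, p)
        raw[-1] += nbinom.sf(cap, dispersion, p)  # top bin absorbs the tail
        return raw / (1.0 - nbinom.pmf(0, dispersion, p))

    def gap(mu: float) -> float:
        q = pmf_for(mu)
        return float(np.dot(ks, q)) - target_mean

    mu = optimize.brentq(gap, 1e-9, 1e4)
    return tuple(float(v) for v in pmf_for(mu))


@lru_cache(maxsize=None)
def _sbt_alpha(p_marginal: float, slope: float) -> float:
    """Logistic intercept so that E_z[expit(alpha + slope*z)] = p_marginal."""
    if not (0.0 < p_marginal < 1.0):
        raise ValueError("marginal endorsement probability must be in (0, 1)")
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def gap(alpha: float) -> float:
        return float(np.dot(weights, expit(alpha + slope * nodes))) - p_marginal

    return optimize.brentq(gap, -40.0, 40.0)


def _widespread_prob_given_count(
    count_pmf: tuple[float, ...],
    g_free: np.ndarray,
    g_forced: np.ndarray,
    p_lower_back: float,
    target: float,
) -> float:
    """Solve the proportionality constant c of P(widespread | count k).

    P(widespread | k, scheme) = min(1, c * g(k)), pinned to 1 where every
    k-set is widespread and to 0 where none is; c is chosen so the mixture
    over the count law and the lower-back forcing hits the target
    CWP-given-chronic probability.
    """
    ks = np.arange(1, MAX_REGIONS + 1)
    pmf = np.asarray(count_pmf)

    def pw(g: np.ndarray, c: float) -> np.ndarray:
        out = np.where(g > 0.0, np.minimum(1.0, c * np.maximum(g, 1e-300)), 0.0)
        out[g >= 1.0] = 1.0
        return out

    def attained(c: float) -> float:
        mix = p_lower_back * pw(g_forced, c) + (1 - p_lower_back) * pw(g_free, c)
        return float(np.dot(pmf, mix))

    lo, hi = attained(0.0), attained(np.inf)
    if not (lo - 1e-12 <= target <= hi + 1e-12):
        raise ValueError(
            f"CWP-given-chronic target {target:.3f} outside attainable "
            f"range [{lo:.3f}, {hi:.3f}] under the count distribution"
        )
    if target >= hi:
        return float("inf")
    del ks
    return optimize.brentq(lambda c: attained(c) - target, 0.0, 1e6)


def _conditional_count_cdf(
    p_chronic: float, rho: float, grid_half_width: float = 8.0, n_grid: int = 4001
) -> tuple[np.ndarray, np.ndarray]:
    """CDF of the count driver v = rho*z + sqrt(1-rho^2)*eps given chronic.

    Chronic status is itself severity-selected (probit-coupled to the same
    z), so v is *not* uniform after the probit transform within the chronic
    subpopulation.  Feeding Phi(v) straight into the count quantile would
    therefore inflate counts.  This tabulates F(x) = P(v <= x | chronic) by
    Gauss-Hermite integration over z; ranking v through it restores a
    uniform driver among chronic respondents while keeping the coupling.
    """
    mix = math.sqrt(1.0 - rho**2)
    t = norm.ppf(1.0 - p_chronic)
    nodes, weights = np.polynomial.hermite_e.hermegauss(96)
    weights = weights / weights.sum()
    p_chronic_given_z = norm.cdf((rho * nodes - t) / mix) if mix > 0 else (
        (rho * nodes > t).astype(float)
    )
    denom = float(np.dot(weights, p_chronic_given_z))
    xgrid = np.linspace(-grid_half_width, grid_half_width, n_grid)
    if mix > 0:
        cond = norm.cdf((xgrid[:, None] - rho * nodes[None, :]) / mix)
    else:
        cond = (xgrid[:, None] >= rho * nodes[None, :]).astype(float)
    fvals = cond @ (weights * p_chronic_given_z) / denom
    return xgrid, np.clip(fvals, 0.0, 1.0)


_MACHINERY_CACHE: dict[tuple, dict] = {}


def _group_cache_key(group: GroupConfig, coupling: float, map_key: tuple) -> tuple:
    return (
        group.age_mean, group.age_sd, group.p_chronic, group.p_lower_back,
        group.p_cwp, group.region_mean, group.region_dispersion,
        group.sbt_item_probs,
        tuple(sorted(group.pro_means.items())),
        tuple(sorted(group.pro_sds.items())),
        coupling, map_key,
    )


def _group_machinery(group: GroupConfig, coupling: float, map_key: tuple):
    """Everything solvable once per (group config, coupling, region map)."""
    cache_key = _group_cache_key(group, coupling, map_key)
    if cache_key in _MACHINERY_CACHE:
        return _MACHINERY_CACHE[cache_key]
    region_map = _REGION_MAP_CACHE[map_key]
    lower_back = frozenset({"lower_back"}) if "lower_back" in region_map else frozenset()
    ks = range(1, MAX_REGIONS + 1)
    g_free = np.array([widespread_probability(k, region_map) for k in ks])
    g_forced = np.array(
        [widespread_probability(k, region_map, lower_back) for k in ks]
    )
    machinery = {
        "age": solve_censored_normal(group.age_mean, group.age_sd, *AGE_RANGE, 1.0),
        "pros": {
            name: solve_censored_normal(
                group.pro_means[name],
                group.pro_sds[name],
                *PRO_RANGES[name],
                PRO_GRANULARITY[name],
                PRO_SIGN[name],
            )
            for name in group.pro_means
        },
        "sbt_alpha": tuple(
            _sbt_alpha(p, 2.0 * coupling) if 0.0 < p < 1.0 else None
            for p in group.sbt_item_probs
        ),
        "g_free": g_free,
        "g_forced": g_forced,
        "lower_back": lower_back,
    }
    if group.p_chronic > 0 and group.region_mean > 0:
        cond_mean = group.region_mean / group.p_chronic
        pmf = _ztnb_capped_pmf(cond_mean, group.region_dispersion)
        machinery["count_pmf"] = pmf
        machinery["count_cdf"] = _conditional_count_cdf(group.p_chronic, coupling)
        machinery["cwp_c"] = _widespread_prob_given_count(
            pmf, g_free, g_forced, group.p_lower_back, group.p_cwp / group.p_chronic
        )
    _MACHINERY_CACHE[cache_key] = machinery
    return machinery


_REGION_MAP_CACHE: dict[tuple, BodyRegionMap] = {}


def _map_key(region_map: BodyRegionMap) -> tuple:
    key = tuple(
        (r.id, r.axial, r.side, r.body_half) for r in region_map.regions
    )
    _REGION_MAP_CACHE[key] = region_map
    return key


# --- region-set construction --------------------------------------------


def _sample_region_set(
    rng: np.random.Generator,
    region_map: BodyRegionMap,
    k: int,
    forced: frozenset[str],
    widespread: bool,
) -> frozenset[str]:
    cats = _categories(region_map)
    all_ids = frozenset(region_map.ids)
    avail = sorted(all_ids - forced)
    if widespread:
        for _ in range(200):
            chosen = set(forced)
            unmet = [c for c in cats.values() if not (c & chosen)]
            ok = True
            while unmet:
                if len(chosen) >= k:
                    ok = False
                    break
                cat = unmet[rng.integers(len(unmet))]
                candidates = sorted(cat - chosen)
                chosen.add(candidates[rng.integers(len(candidates))])
                unmet = [c for c in cats.values() if not (c & chosen)]
            if not ok:
                continue
            rest = sorted(all_ids - chosen)
            extra = rng.choice(len(rest), size=k - len(chosen), replace=False)
            chosen.update(rest[i] for i in extra)
            return frozenset(chosen)
        raise RuntimeError(f"cannot build a widespread set of size {k}")
    avoidable = [
        c
        for c in cats.values()
        if not (c & forced) and len(all_ids - forced - c) >= k - len(forced)
    ]
    if not avoidable:
        raise RuntimeError(f"every set of size {k} with {sorted(forced)} is widespread")
    cat = avoidable[rng.integers(len(avoidable))]
    pool = sorted(all_ids - forced - cat)
    picks = rng.choice(len(pool), size=k - len(forced), replace=False)
    return frozenset(forced | {pool[i] for i in picks})


# --- main entry points --------------------------------------------------


def _generate_group(
    rng: np.random.Generator,
    group: GroupConfig,
    cfg: GeneratorConfig,
    region_map: BodyRegionMap,
    n: int,
    lbp_answer: Optional[bool],
    id_start: int,
) -> list[IndividualRecord]:
    mach = _group_machinery(group, cfg.coupling, _map_key(region_map))
    rho = cfg.coupling
    mix = math.sqrt(1.0 - rho**2)
    records = []
    for i in range(n):
        z = rng.standard_normal()
        rid = f"ind_{id_start + i:05d}"

        sex = "female" if rng.random() < group.p_women else "male"
        age = float(mach["age"].sample(np.array([rng.standard_normal()]))[0])

        # chronic pain: probit-coupled to severity, marginal p_chronic
        chronic = norm.cdf(rho * z + mix * rng.standard_normal()) > 1.0 - group.p_chronic

        regions: frozenset[str] = frozenset()
        if chronic and "count_pmf" in mach:
            v = rho * z + mix * rng.standard_normal()
            xgrid, fvals = mach["count_cdf"]
            u = float(np.interp(v, xgrid, fvals))
            pmf = np.asarray(mach["count_pmf"])
            k = int(np.searchsorted(np.cumsum(pmf), u) + 1)
            k = min(k, MAX_REGIONS)
            force_lb = bool(mach["lower_back"]) and rng.random() < group.p_lower_back
            forced = mach["lower_back"] if force_lb else frozenset()
            g = (mach["g_forced"] if force_lb else mach["g_free"])[k - 1]
            c = mach["cwp_c"]
            p_wide = 1.0 if g >= 1.0 else min(1.0, c * g) if g > 0 else 0.0
            wide = rng.random() < p_wide
            regions = _sample_region_set(rng, region_map, k, forced, wide)

        sbt_items: Optional[tuple[int, ...]] = tuple(
            int(rng.random() < (expit(a + 2.0 * rho * z) if a is not None else p))
            for a, p in zip(mach["sbt_alpha"], group.sbt_item_probs)
        )

        pros = {}
        for name, marg in mach["pros"].items():
            if cfg.pro_missing and rng.random() < cfg.pro_missing:
                pros[name] = None
                continue
            g_i = rho * z + mix * rng.standard_normal()
            pros[name] = float(marg.sample(np.array([g_i]))[0])

        chronic_out: Optional[bool] = bool(chronic)
        regions_out: Optional[frozenset[str]] = regions
        if cfg.mannequin_missing and rng.random() < cfg.mannequin_missing:
            chronic_out, regions_out = None, None
        if cfg.sbt_missing and rng.random() < cfg.sbt_missing:
            sbt_items = None

        records.append(
            IndividualRecord(
                id=rid,
                age=age,
                sex=sex,
                lbp_last_week=lbp_answer,
                sbt_items=sbt_items,
                chronic_pain=chronic_out,
                regions=regions_out,
                **pros,
            )
        )
    return records


def generate_cohort(
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
    region_map: Optional[BodyRegionMap] = None,
) -> Cohort:
    """Draw one synthetic cohort; fully reproducible for a fixed seed.

    The cohort holds ``lbp.n`` records answering yes to the last-week LBP
    question, ``reference.n`` answering no, and ``n_unassigned`` leaving it
    blank (drawn from either group's parameters at random).
    """
    config = config or GeneratorConfig.default()
    region_map = region_map or default_region_map()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    records = []
    records += _generate_group(
        rng, config.lbp, config, region_map, config.lbp.n, True, 1
    )
    records += _generate_group(
        rng, config.reference, config, region_map, config.reference.n, False,
        1 + config.lbp.n,
    )
    n_assigned = config.lbp.n + config.reference.n
    share = config.lbp.n / n_assigned if n_assigned else 0.5
    for j in range(config.n_unassigned):
        src = config.lbp if rng.random() < share else config.reference
        records += _generate_group(
            rng, src, config, region_map, 1, None, 1 + n_assigned + j
        )
    return Cohort(tuple(records), region_map)


def recover_parameters(
    cohort: Cohort, config: GeneratorConfig, z_flag: float = 4.0
) -> pd.DataFrame:
    """Compare sample estimates against the configured generating values.

    One row per (group, quantity): configured value, complete-case sample
    estimate, standard error, z-score, and a flag for |z| above ``z_flag``.
    """
    df = scored_frame(cohort)
    chronic_by_id = {r.id: r.chronic_pain for r in cohort}
    df["chronic"] = df["id"].map(chronic_by_id)
    rows = []
    for gname, gcfg in [("lbp", config.lbp), ("reference", config.reference)]:
        sub = df[df["group"] == gname]

        def add_mean(quantity: str, column: str, configured: float) -> None:
            vals = pd.to_numeric(sub[column], errors="coerce").dropna()
            est = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append((gname, quantity, configured, est, len(vals), se))

        def add_prop(quantity: str, flags: pd.Series, configured: float) -> None:
            flags = flags.dropna().astype(bool)
            n = len(flags)
            est = float(flags.mean()) if n else np.nan
            se = float(np.sqrt(est * (1 - est) / n)) if n else np.nan
            rows.append((gname, quantity, configured, est, n, se))

        add_mean("age", "age", gcfg.age_mean)
        add_prop("p_women", sub["sex"].map({"female": True, "male": False}), gcfg.p_women)
        add_prop("p_chronic", sub["chronic"], gcfg.p_chronic)
        add_prop(
            "p_cwp",
            sub["pain_status"].map(lambda s: pd.NA if s is pd.NA else s == "CWP"),
            gcfg.p_cwp,
        )
        add_mean("region_mean", "region_count", gcfg.region_mean)
        add_mean("sbt_mean", "sbt_overall", float(sum(gcfg.sbt_item_probs)))
        for name in gcfg.pro_means:
            add_mean(name, name, gcfg.pro_means[name])

    out = pd.DataFrame(
        rows, columns=["group", "quantity", "configured", "estimate", "n", "se"]
    )
    out["z"] = (out["estimate"] - out["configured"]) / out["se"]
    out["flag"] = out["z"].abs() > z_flag
    return out
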