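"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator draws each sex-by-status group from a correlated multivariate
normal whose per-analyte means and SDs default to the study's printed group
summaries (SD reconstructed as SEM x sqrt(n)); globulin is derived per fish
as TP - ALB exactly, vet scores are assigned consistently with the
healthy/diseased split, and the study's missing-data topology (BA sporadic,
UA absent, one missing CK) can be injected on top.  ``plant_effects``
rewrites a config so that only chosen variables separate the health
classes, supporting parameter-recovery and null-calibration experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .analytes import ANALYTES, MORPHO_TRAITS
from .cohort import Cohort, FishRecord

__all__ = [
    "GroupParams",
    "GeneratorConfig",
    "default_config",
    "generate_cohort",
    "plant_effects",
    "inject_study_artifacts",
]

#: Analytes drawn from the multivariate normal (GLOB derived, UA absent).
DRAWN_ANALYTES: tuple[str, ...] = ("AST", "BA", "CK", "GLU", "PHOS", "Ca",
                                   "TP", "ALB", "K", "Na")

#: Diseased vet-score grades (1-5 on the 0.5 grid) and the geometric decay
#: ratio that makes low grades dominate.
DISEASED_GRADES = np.round(1.0 + 0.5 * np.arange(9), 1)
DISEASED_GRADE_RATIO = 0.6

MORPHO_SD_FRACTION = 0.10  # default morphometric SD as a fraction of the mean


@dataclass
class GroupParams:
    """Location/scale parameters for one sex-by-status group."""

    sex: str
    status: str  # healthy | diseased
    n: int
    analyte_means: dict[str, float]
    analyte_sds: dict[str, float]
    morpho_means: dict[str, float]
    morpho_sds: dict[str, float]
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for code, sd in {**self.analyte_sds, **self.morpho_sds}.items():
            if sd < 0:
                raise ValueError(f"{code}: negative SD")


@dataclass
class GeneratorConfig:
    """Everything needed to draw a cohort reproducibly."""

    groups: list[GroupParams]
    correlation: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    n_scale: int = 1
    truncation: str = "none"  # none | instrument_range
    healthy_scores: tuple[float, ...] = (0.0, 0.5)
    diseased_grade_ratio: float = DISEASED_GRADE_RATIO

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "sex": g.sex, "status": g.status, "n": g.n,
                    "analyte_means": dict(g.analyte_means),
                    "analyte_sds": dict(g.analyte_sds),
                    "morpho_means": dict(g.morpho_means),
                    "morpho_sds": dict(g.morpho_sds),
                    "missing_rates": dict(g.missing_rates),
                }
                for g in self.groups
            ],
            "correlation": [list(c) for c in self.correlation],
            "seed": self.seed,
            "n_scale": self.n_scale,
            "truncation": self.truncation,
            "healthy_scores": list(self.healthy_scores),
            "diseased_grade_ratio": self.diseased_grade_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            groups=[GroupParams(**g) for g in d["groups"]],
            correlation=[tuple(c) for c in d.get("correlation", [])],
            seed=int(d.get("seed", 0)),
            n_scale=int(d.get("n_scale", 1)),
            truncation=d.get("truncation", "none"),
            healthy_scores=tuple(d.get("healthy_scores", (0.0, 0.5))),
            diseased_grade_ratio=float(d.get("diseased_grade_ratio", DISEASED_GRADE_RATIO)),
        )


def default_config(n_scale: int = 1, seed: int = 0) -> GeneratorConfig:
    """Generator defaults encoding the study's printed group summaries."""
    raw = yaml.safe_load(
        resources.files("steatnet.data").joinpath("table1_default.yaml").read_text()
    )
    groups = []
    for _, g in raw["groups"].items():
        n = int(g["n"])
        means, sds = {}, {}
        for code, (mean, sem) in g["analytes"].items():
            means[code] = float(mean)
            sds[code] = float(sem) * np.sqrt(n)  # SD reconstructed from the printed SEM
        morpho_means = {k: float(v) for k, v in g["morpho"].items()}
        morpho_sds = {k: MORPHO_SD_FRACTION * abs(v) for k, v in morpho_means.items()}
        groups.append(GroupParams(
            sex=g["sex"], status=g["status"], n=n,
            analyte_means=means, analyte_sds=sds,
            morpho_means=morpho_means, morpho_sds=morpho_sds,
        ))
    correlation = [(a, b, float(r)) for a, b, r in raw.get("correlation", [])]
    return GeneratorConfig(groups=groups, correlation=correlation,
                           seed=seed, n_scale=n_scale)


def _covariance(codes: list[str], sds: dict[str, float],
                correlation: list[tuple[str, str, float]]) -> np.ndarray:
    sd = np.array([sds[c] for c in codes])
    cov = np.diag(sd ** 2)
    idx = {c: i for i, c in enumerate(codes)}
    for a, b, rho in correlation:
        if a in idx and b in idx:
            cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = rho * sds[a] * sds[b]
    # Degenerate (zero-SD) dimensions are fine; validate the rest.
    live = sd > 0
    if live.any():
        sub = cov[np.ix_(live, live)]
        eig = np.linalg.eigvalsh(sub)
        if eig.min() < -1e-9 * max(eig.max(), 1.0):
            bad = ", ".join(f"{a}-{b}" for a, b, _ in correlation)
            raise ValueError(f"infeasible correlation matrix (pairs: {bad})")
    return cov


def _draw_group(rng: np.random.Generator, group: GroupParams,
                config: GeneratorConfig, n: int) -> np.ndarray:
    codes = [c for c in DRAWN_ANALYTES if c in group.analyte_means]
    means = np.array([group.analyte_means[c] for c in codes])
    cov = _covariance(codes, group.analyte_sds, config.correlation)
    # Cholesky needs strict positive definiteness; degenerate (zero-SD)
    # configurations fall back to the eigendecomposition sampler.
    eig = np.linalg.eigvalsh(cov)
    method = "cholesky" if eig.min() > 1e-12 * max(eig.max(), 1.0) else "eigh"
    i_tp = codes.index("TP") if "TP" in codes else None
    i_alb = codes.index("ALB") if "ALB" in codes else None

    def valid(rows: np.ndarray) -> np.ndarray:
        ok = (rows > 0).all(axis=1)
        if i_tp is not None and i_alb is not None:
            ok &= rows[:, i_tp] > rows[:, i_alb]  # globulin must stay positive
        if config.truncation == "instrument_range":
            for j, c in enumerate(codes):
                spec = ANALYTES[c]
                ok &= (rows[:, j] >= spec.range_low) & (rows[:, j] <= spec.range_high)
        return ok

    rows = rng.multivariate_normal(means, cov, size=n, method=method)
    for _ in range(1000):
        bad = ~valid(rows)
        if not bad.any():
            break
        rows[bad] = rng.multivariate_normal(means, cov, size=int(bad.sum()),
                                            method=method)
    else:
        raise RuntimeError("could not draw valid analyte values; check config")
    return rows, codes


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Draw a cohort from the configured group parameters.

    Per group: analytes come from a correlated multivariate normal
    (negative draws — and, under instrument-range truncation, out-of-range
    draws — are redrawn), GLOB is set to TP - ALB exactly, morphometrics
    are drawn independently (ages rounded to whole years), vet scores are
    assigned consistently with the group's status, and per-analyte
    missingness is injected at the configured rates.  Identical config and
    seed give identical cohorts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[FishRecord] = []
    counter = 0
    for group in config.groups:
        n = group.n * config.n_scale
        rows, codes = _draw_group(rng, group, config, n)

        def draw_morpho(trait: str, positive: bool = True) -> np.ndarray:
            mean = group.morpho_means[trait]
            sd = group.morpho_sds.get(trait, 0.0)
            vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
            if positive:
                for _ in range(1000):
                    bad = vals <= 0
                    if not bad.any():
                        break
                    vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            return vals

        lengths = draw_morpho("total_length")
        weights = draw_morpho("weight")
        ages = np.maximum(np.rint(draw_morpho("age")), 1).astype(int)

        if group.status == "healthy":
            scores = rng.choice(np.asarray(config.healthy_scores, dtype=float), size=n)
        else:
            probs = config.diseased_grade_ratio ** np.arange(len(DISEASED_GRADES))
            probs /= probs.sum()
            scores = rng.choice(DISEASED_GRADES, size=n, p=probs)

        miss = {
            code: rng.random(n) < rate
            for code, rate in group.missing_rates.items()
        }

        for i in range(n):
            counter += 1
            analytes: dict[str, float | None] = {
                c: float(rows[i, j]) for j, c in enumerate(codes)
            }
            if "TP" in analytes and "ALB" in analytes:
                analytes["GLOB"] = analytes["TP"] - analytes["ALB"]
            for code, mask in miss.items():
                if mask[i]:
                    analytes[code] = None
            records.append(FishRecord(
                fish_id=f"SY{counter:04d}",
                sex=group.sex,
                total_length=float(lengths[i]),
                weight=float(weights[i]),
                vet_score=float(scores[i]),
                age=int(ages[i]),
                analytes=analytes,
            ))
    return Cohort(records, provenance="synthetic:table1-defaults")


def _pooled(values: list[tuple[float, float, int]]) -> tuple[float, float]:
    """Weighted pooled mean and RMS-pooled SD from (mean, sd, n) triples."""
    ns = np.array([n for _, _, n in values], dtype=float)
    means = np.array([m for m, _, _ in values])
    sds = np.array([s for _, s, _ in values])
    w = ns / ns.sum()
    return float(w @ means), float(np.sqrt(w @ (sds ** 2)))


def plant_effects(
    config: GeneratorConfig,
    informative: list[str] | tuple[str, ...],
    null_shift: bool = False,
) -> GeneratorConfig:
    """Equalize every variable except the named informative ones.

    Non-informative variables are pooled across health classes within each
    sex (preserving dimorphism structure); ``null_shift=True`` pools every
    variable across all four groups — a clean global null.  An empty
    informative list without ``null_shift`` returns the config unchanged.

    Note: GLOB is derived (TP - ALB) and therefore inherits whatever
    separation TP and ALB carry; it cannot be planted or nulled on its own.
    """
    known = set(DRAWN_ANALYTES) | set(MORPHO_TRAITS)
    unknown = set(informative) - known
    if unknown:
        raise KeyError(f"unknown variable code(s): {sorted(unknown)}")
    if not informative and not null_shift:
        return config
    new = copy.deepcopy(config)
    informative = set() if null_shift else set(informative)

    def pools(groups: list[GroupParams]):
        for var in known:
            if var in informative:
                continue
            if var in DRAWN_ANALYTES:
                triples = [
                    (g.analyte_means[var], g.analyte_sds[var], g.n)
                    for g in groups if var in g.analyte_means
                ]
                if not triples:
                    continue
                mean, sd = _pooled(triples)
                for g in groups:
                    if var in g.analyte_means:
                        g.analyte_means[var] = mean
                        g.analyte_sds[var] = sd
            else:
                triples = [
                    (g.morpho_means[var], g.morpho_sds.get(var, 0.0), g.n)
                    for g in groups if var in g.morpho_means
                ]
                if not triples:
                    continue
                mean, sd = _pooled(triples)
                for g in groups:
                    if var in g.morpho_means:
                        g.morpho_means[var] = mean
                        g.morpho_sds[var] = sd
    if null_shift:
        pools(new.groups)
    else:
        for sex in ("male", "female"):
            pools([g for g in new.groups if g.sex == sex])
    return new


def inject_study_artifacts(cohort: Cohort, seed: int = 0, ba_rate: float = 0.2) -> Cohort:
    """Overlay the study's missing-data topology on a generated cohort.

    Bile acids go missing for a random subset of fish (default rate 0.2),
    uric acid is removed everywhere (never detected in this species), and
    exactly one random fish loses its CK value — the record that later
    drops out of the complete-case modeling cohort.
    """
    if len(cohort) < 2:
        raise ValueError("cohort too small to inject artifacts")
    rng = np.random.default_rng(seed)
    ba_mask = rng.random(len(cohort)) < ba_rate
    ck_victim = int(rng.integers(len(cohort)))
    records = []
    for i, r in enumerate(cohort.records):
        analytes = dict(r.analytes)
        analytes["UA"] = None
        if ba_mask[i]:
            analytes["BA"] = None
        if i == ck_victim:
            analytes["CK"] = None
        records.append(FishRecord(
            fish_id=r.fish_id, sex=r.sex, total_length=r.total_length,
            weight=r.weight, vet_score=r.vet_score, age=r.age,
            analytes=analytes,
        ))
    return Cohort(records, provenance=cohort.provenance + "+artifacts")


def save_config(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def load_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))
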