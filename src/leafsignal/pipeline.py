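"""End-to-end analysis pipeline: simulate -> colour -> survey -> experiments.

`run_pipeline` chains the synthetic survey, the correlation screen with
Benjamini-Hochberg control at q = 0.05, the presence GLMMs (one colour
channel per model, adjusted at q = 0.1 with marginal R-squared per model),
and the greenhouse choice/performance analyses, into one machine-readable
report with a provenance block (seed, config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .experiments import compare_performance, exact_binomial_two_tailed
from .simulate import (
    PerformanceConfig,
    SimConfig,
    generate_choice_trials,
    generate_field_survey,
    generate_performance,
)
from .survey import (
    APHID_COUNTIES,
    COLOUR_CHANNELS,
    GS_NAMES,
    bh_adjust,
    fit_presence_glmm,
    lrt_drop_term,
    marginal_r2,
    spearman_matrix,
)

__all__ = ["RunConfig", "run_pipeline"]

#: colour channels tested per herbivore presence model
PRESENCE_CHANNELS = {
    "pieris": ("bg_ratio", "prg_ratio", "drg_ratio"),
    "brassicae": ("bg_ratio", "brightness"),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    illuminant: str = "flat"
    fdr_correlations: float = 0.05
    fdr_presence: float = 0.10
    n_choice_pairs: int = 30
    p_choose_high: float = 0.5
    run_experiments: bool = True
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.illuminant not in ("flat", "d65"):
            raise ValueError(f"illuminant: unknown value {self.illuminant!r} (use 'flat' or 'd65')")
        for name in ("fdr_correlations", "fdr_presence"):
            q = getattr(self, name)
            if not 0 < q < 1:
                raise ValueError(f"{name}: must be in (0, 1), got {q}")


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    payload = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage on synthetic data and return the JSON-able report."""
    rng = np.random.default_rng(cfg.seed)
    sim_cfg = cfg.sim if cfg.sim is not None else SimConfig(seed=cfg.seed, illuminant=cfg.illuminant)
    records = generate_field_survey(sim_cfg, rng)

    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "version": __version__,
            "n_plants": int(len(records)),
        }
    }

    # Correlation screen: colour channels x glucosinolates, BH at q = 0.05.
    corr = spearman_matrix(records, list(COLOUR_CHANNELS), list(GS_NAMES))
    valid = corr["p"].notna()
    reject = np.zeros(len(corr), dtype=bool)
    padj = np.full(len(corr), np.nan)
    if valid.any():
        rej, adj = bh_adjust(corr.loc[valid, "p"], cfg.fdr_correlations)
        reject[valid.to_numpy()] = rej
        padj[valid.to_numpy()] = adj
    corr["p_adjusted"] = padj
    corr["significant"] = reject
    report["correlation_screen"] = corr.to_dict(orient="records")

    # Presence GLMMs: single colour predictor per model, BH at q = 0.1.
    presence: dict = {}
    pvals: list[float] = []
    keys: list[tuple[str, str]] = []
    for herbivore, channels in PRESENCE_CHANNELS.items():
        county_filter = APHID_COUNTIES if herbivore == "brassicae" else None
        presence[herbivore] = {}
        for ch in channels:
            full = fit_presence_glmm(records, herbivore, [ch], county_filter=county_filter)
            null = fit_presence_glmm(records, herbivore, [], county_filter=county_filter)
            if not (full.ok and null.ok):
                presence[herbivore][ch] = {"flags": list(full.flags + null.flags)}
                continue
            test = lrt_drop_term(full, null, df=1)
            presence[herbivore][ch] = {
                "beta": full.coef(ch),
                "se": float(full.se[full.terms.index(ch)]),
                "chi2": test.statistic,
                "p": test.p_value,
                "marginal_r2": marginal_r2(full),
                "sigma_county": full.sigma_county,
                "sigma_pop": full.sigma_pop,
                "n": full.n,
            }
            pvals.append(test.p_value)
            keys.append((herbivore, ch))
    if pvals:
        rej, adj = bh_adjust(pvals, cfg.fdr_presence)
        for (herb, ch), r, a in zip(keys, rej, adj):
            presence[herb][ch]["p_adjusted"] = float(a)
            presence[herb][ch]["significant"] = bool(r)
    report["presence_models"] = presence

    if cfg.run_experiments:
        choice = {}
        for metric in ("bg_ratio", "drg_ratio", "brightness"):
            trials = generate_choice_trials(cfg.n_choice_pairs, cfg.p_choose_high, rng, metric)
            k = int((trials["chosen"] == "high").sum())
            choice[metric] = {
                "chose_high": k,
                "n": int(len(trials)),
                "p": exact_binomial_two_tailed(k, len(trials)),
            }
        report["choice_tests"] = choice

        perf = generate_performance(PerformanceConfig(), rng)
        perf_results = {}
        for resp, transform in (
            ("growth_rate", "none"),
            ("pupal_mass_mg", "none"),
            ("time_to_pupation_days", "log"),
        ):
            res = compare_performance(perf.larvae, resp, transform=transform)
            perf_results[resp] = {
                "F": res.statistic,
                "df": list(res.df),
                "p": res.p_value,
                "transform": transform,
                "group_stats": res.fit_info.get("group_stats"),
            }
        report["performance_models"] = perf_results

    return report


def summarise(report: dict) -> str:
    """Human-readable summary table of a pipeline report."""
    lines = [
        f"leafsignal {report['provenance']['version']}  seed={report['provenance']['seed']}  "
        f"n_plants={report['provenance']['n_plants']}",
        "",
        "Presence models (colour channel, beta, chi2, p, adj-significant, marginal R2):",
    ]
    for herb, models in report.get("presence_models", {}).items():
        for ch, m in models.items():
            if "beta" not in m:
                lines.append(f"  {herb:10s} {ch:11s} FAILED {m.get('flags')}")
                continue
            sig = "yes" if m.get("significant") else "no"
            lines.append(
                f"  {herb:10s} {ch:11s} beta={m['beta']:+.3f} chi2={m['chi2']:.2f} "
                f"p={m['p']:.3g} adj={sig} R2m={m['marginal_r2']:.3f}"
            )
    n_sig = sum(1 for row in report.get("correlation_screen", []) if row.get("significant"))
    lines.append("")
    lines.append(f"Correlation screen: {n_sig} colour-GS pairs significant after BH.")
    for metric, c in report.get("choice_tests", {}).items():
        lines.append(f"Choice {metric}: {c['chose_high']}/{c['n']} chose high, p={c['p']:.3g}")
    for resp, m in report.get("performance_models", {}).items():
        lines.append(f"Performance {resp}: F={m['F']:.2f}, p={m['p']:.3g}")
    return "\n".join(lines)
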