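"""Procedure comparison and plot-ready report datasets.

Compares frequentist (q-value) and Bayesian (classification-probability)
screens area by area: 2x2 cross-tabulation of flags, proportion of specific
agreement for the positive category, quantile-quantile datasets (empirical
-log p against Exponential(1); ordered q-values against ordered posterior
classification probabilities), and an end-to-end pipeline that runs the whole
analysis from a config mapping and writes a reproducible report bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .areal import AreaTable, read_adjacency, read_area_table
from .mixture import McmcConfig, MixtureModelSpec, fit_mixture, summarize_posterior
from .screen import funnel_limits, screen_table
from .simulate import generate_map

__all__ = [
    "CrossTab",
    "cross_tabulate",
    "specific_agreement",
    "qq_exponential",
    "rank_agreement",
    "run_pipeline",
]


@dataclass
class CrossTab:
    """2x2 agreement table between two flagging procedures.

    ``a`` areas flagged by both, ``b`` only by the first, ``c`` only by the
    second, ``n_neither`` by neither; a + b + c + n_neither = m.
    """

    a: int
    b: int
    c: int
    n_neither: int
    label_1: str = "procedure_1"
    label_2: str = "procedure_2"

    @property
    def m(self) -> int:
        return self.a + self.b + self.c + self.n_neither

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.a, self.b], [self.c, self.n_neither]],
            index=pd.Index(["yes", "no"], name=self.label_1),
            columns=pd.Index(["yes", "no"], name=self.label_2),
        )


def cross_tabulate(flags_1, flags_2, labels=("procedure_1", "procedure_2")) -> CrossTab:
    """Cross-tabulate two 0/1 rejection vectors over the same areas."""
    f1 = np.asarray(flags_1, dtype=int)
    f2 = np.asarray(flags_2, dtype=int)
    if f1.shape != f2.shape:
        raise ValueError("flag vectors must have equal length")
    a = int(((f1 == 1) & (f2 == 1)).sum())
    b = int(((f1 == 1) & (f2 == 0)).sum())
    c = int(((f1 == 0) & (f2 == 1)).sum())
    return CrossTab(a, b, c, int(f1.size) - a - b - c, labels[0], labels[1])


def specific_agreement(tab: CrossTab) -> float:
    """Proportion of specific agreement for the flagged category,
    p_s = 2a / (2a + b + c), as a fraction in [0, 1].

    Unlike raw agreement it ignores the (dominant) doubly-negative cell, so
    it is the appropriate summary when flags are rare.  Undefined when no
    area is flagged by either procedure.
    """
    denom = 2 * tab.a + tab.b + tab.c
    if denom == 0:
        raise ValueError("specific agreement undefined: no area flagged by either procedure")
    return 2.0 * tab.a / denom


def qq_exponential(pvals, cap: float = 1e-300) -> pd.DataFrame:
    """Q-Q dataset of -log(p) order statistics against Exponential(1).

    Under the global null p is uniform so -log(p) is Exp(1) and points fall
    on the bisector; divergent areas push the largest pairs above it.
    Theoretical quantiles use plotting positions (i - 0.5)/m.  Zero p-values
    are capped (with a warning) before the log.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("p-values of exactly 0 capped before log transform")
        p = np.maximum(p, cap)
    m = p.size
    emp = np.sort(-np.log(p))
    theo = -np.log1p(-(np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame({"theoretical": theo, "empirical": emp})


def rank_agreement(q, probs) -> tuple[pd.DataFrame, float]:
    """Ordered q-values paired with ordered classification probabilities,
    plus the Spearman rank correlation of the (unsorted) inputs.

    Points on the bisector mean the two criteria rank the areas identically;
    the correlation coefficient is an added scalar summary of the same idea.
    """
    q = np.asarray(q, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if q.shape != probs.shape:
        raise ValueError("inputs must have equal length")
    pairs = pd.DataFrame({"q_sorted": np.sort(q), "prob_sorted": np.sort(probs)})
    rho = float(stats.spearmanr(q, probs).statistic)
    return pairs, rho


# ---------------------------------------------------------------------------
# End-to-end pipeline


_DEFAULTS = {
    "alpha": 0.05,
    "fdr_level": 0.05,
    "lambda": 0.5,
    "q_cutoff": 0.20,
    "prob_cutoff": 0.20,
    "inclusion_cutoff": 0.90,
    "models": ["pg"],
    "c": 9.7,
    "d": 0.3,
    "chains": 2,
    "burnin": 1000,
    "store": 1000,
    "thin": 1,
    "seed": 0,
}


def run_pipeline(config: dict, outdir) -> dict:
    """Run screen -> mixture fit(s) -> comparison and write a report bundle.

    ``config`` either names input files (``area_table``, optionally
    ``adjacency``/``adjacency_dialect``) or requests a synthetic map
    (``simulate: {...generate_map kwargs...}``).  Writes per-area results,
    cross-tabulations with specific agreement, funnel/Q-Q datasets and a
    manifest echoing every setting, then returns the bundle as a dict.
    Identical config (including seed) reproduces identical numbers.
    """
    cfg = {**_DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    adj = None
    truth = None
    if "simulate" in cfg:
        smap = generate_map(**cfg["simulate"])
        table, adj, truth = smap.table, smap.adj, smap.truth
    elif "area_table" in cfg:
        table = read_area_table(cfg["area_table"])
        if cfg.get("adjacency"):
            adj = read_adjacency(cfg["adjacency"],
                                 dialect=cfg.get("adjacency_dialect", "edge-list"),
                                 table=table)
    else:
        raise ValueError("config must provide 'area_table' or 'simulate'")
    if "bym" in cfg["models"] and adj is None:
        raise ValueError("BYM model requested but no adjacency was configured "
                         "(set 'adjacency' or use a simulated map)")

    res = screen_table(table, alpha=cfg["alpha"], fdr_level=cfg["fdr_level"],
                       lam=cfg["lambda"], q_cutoffs=(0.05, 0.10, cfg["q_cutoff"]))
    per_area = res.to_frame()

    e_grid = np.geomspace(table.e.min(), table.e.max(), 80)
    funnel = funnel_limits(e_grid, alpha=cfg["alpha"]).to_frame()
    funnel_q = funnel_limits(e_grid, pvals=res.p, q_threshold=cfg["q_cutoff"],
                             pi0_hat=res.pi0_hat).to_frame()
    qq_p = qq_exponential(res.p)

    mcmc = McmcConfig(n_chains=cfg["chains"], n_burnin=cfg["burnin"],
                      n_store=cfg["store"], thin=cfg["thin"], seed=cfg["seed"])
    q_flags = (res.q <= cfg["q_cutoff"]).astype(int)
    comparisons = {}
    qq_rank = {}
    for model in cfg["models"]:
        spec = MixtureModelSpec(variant=model, c=cfg["c"], d=cfg["d"])
        draws = fit_mixture(table, adj, spec, mcmc)
        summ = summarize_posterior(draws)
        frame = summ.frame
        prob_null = frame["prob_null"].to_numpy()
        frame["flag_prob"] = (prob_null <= cfg["prob_cutoff"]).astype(int)
        frame["flag_inclusion"] = (frame["prob_divergent"] >= cfg["inclusion_cutoff"]).astype(int)
        per_area = per_area.merge(frame.add_prefix(f"{model}_").rename(
            columns={f"{model}_area_id": "area_id"}), on="area_id")
        tab = cross_tabulate(frame["flag_prob"], q_flags,
                             labels=(f"{model}<= {cfg['prob_cutoff']}", f"q<={cfg['q_cutoff']}"))
        try:
            ps = specific_agreement(tab)
        except ValueError:
            ps = None  # undefined: no area flagged by either procedure
        pairs, rho = rank_agreement(res.q, prob_null)
        comparisons[model] = {"crosstab": {"a": tab.a, "b": tab.b, "c": tab.c,
                                           "n_neither": tab.n_neither},
                              "specific_agreement": ps,
                              "spearman_q_vs_prob": rho,
                              "max_psrf": summ.max_psrf}
        qq_rank[model] = pairs

    per_area.to_csv(outdir / "per_area.csv", index=False)
    funnel.to_csv(outdir / "funnel_limits.csv", index=False)
    funnel_q.to_csv(outdir / "funnel_limits_qadjusted.csv", index=False)
    qq_p.to_csv(outdir / "qq_exponential.csv", index=False)
    for model, pairs in qq_rank.items():
        pairs.to_csv(outdir / f"qq_rank_{model}.csv", index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)

    manifest = {"package_version": __version__, "config": cfg,
                "m": table.m, "pi0_hat": res.pi0_hat,
                "n_rejections": res.n_rejections,
                "comparisons": comparisons}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
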