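"""End-to-end analysis: chunk both registers, build word measures, correlate.

The pipeline reproduces the full comparison structure of the study
design on any pair of corpora plus a transcript set and an RT table:

1. run the BTP chunker and the random baseline on the child-directed
   (CDS) and adult-directed (ADS) corpora;
2. select target words attested in both corpora with both an AoFP and an
   RT estimate, and assemble the per-word measure table
   (``freq_*``, ``n_mwus_*``, ``n_baseline_*``, ``aofp``, ``rt``);
3. compute full and partial Kendall tau-b for every predictor x response
   cell, with percentile-bootstrap CIs — the partial control is #Freq
   when testing #MWUs/#baseline, and #MWUs when testing #Freq, always
   from the same register as the predictor;
4. compute paired-bootstrap CIs for the study's three families of
   coefficient contrasts: register contrasts per response
   (ADS-vs-CDS variants), chunker-vs-baseline contrasts on the
   designated response (ADS predictors with RT, CDS predictors with
   AoFP), and cross-response contrasts (ADS predictor on RT vs the CDS
   counterpart on AoFP).  All contrasts are differences of coefficient
   magnitudes, so "facilitatory direction" means a positive difference
   between two negative correlations.

Everything is deterministic given the master seed, which fans out to
named sub-seeds (baseline chunkers, MLU bootstrap, correlation
bootstraps) so components can be rerun in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from mwulex.aofp import assign_aofp, estimate_mlus
from mwulex.chunker import ChunkerConfig, UnitInventory, run_baseline, run_cbl
from mwulex.correlations import (
    DegenerateRankingError,
    IntervalEstimate,
    TauResult,
    bootstrap_ci,
    bootstrap_difference_ci,
    kendall_tau_b,
    partial_tau_b,
)
from mwulex.corpus_io import Corpus, TranscriptSet
from mwulex.mwu_stats import count_units_per_word, select_target_words, word_frequencies

__all__ = ["PipelineConfig", "AnalysisResult", "run_analysis", "build_measures"]

PREDICTORS = [
    "freq_ads", "freq_cds",
    "n_mwus_ads", "n_mwus_cds",
    "n_baseline_ads", "n_baseline_cds",
]
RESPONSES = ["rt", "aofp"]

# partial-correlation control per predictor: frequency controls the unit
# counts, unit counts control frequency — register always matches
CONTROL = {
    "freq_ads": "n_mwus_ads",
    "freq_cds": "n_mwus_cds",
    "n_mwus_ads": "freq_ads",
    "n_mwus_cds": "freq_cds",
    "n_baseline_ads": "freq_ads",
    "n_baseline_cds": "freq_cds",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    reps: int = 1000            # bootstrap replicates for every CI
    mlu_reps: int = 1000        # bootstrap replicates per transcript MLU
    min_unit_length: int = 2    # units shorter than this never count toward #MWUs
    baseline_attach_prob: float = 0.5
    threshold_mode: str = "global_mean"


def _subseed(master: int, component: int) -> int:
    return int(np.random.SeedSequence([master, component]).generate_state(1)[0] % (2**31))


@dataclass
class CellResult:
    """One predictor x response x mode correlation."""

    predictor: str
    response: str
    mode: str                     # "full" | "partial"
    control: str | None
    tau: TauResult | None         # None when undefined (degenerate ranking)
    ci: IntervalEstimate | None
    partial_point: float | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "predictor": self.predictor,
            "response": self.response,
            "mode": self.mode,
            "control": self.control,
        }
        if self.tau is None and self.partial_point is None:
            d["undefined"] = True
            return d
        if self.mode == "full":
            assert self.tau is not None
            d["tau"] = self.tau.tau
            d["P"] = self.tau.concordant
            d["Q"] = self.tau.discordant
            d["X0"] = self.tau.ties_x_only
            d["Y0"] = self.tau.ties_y_only
        else:
            d["tau"] = self.partial_point
        if self.ci is not None:
            d["ci"] = [self.ci.lower, self.ci.upper]
        return d


@dataclass
class ComparisonResult:
    """Paired-bootstrap contrast between two coefficient magnitudes."""

    name: str
    analysis: str                 # "register" | "baseline" | "cross_response"
    mode: str                     # "full" | "partial"
    ci: IntervalEstimate

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "analysis": self.analysis,
            "mode": self.mode,
            "point": self.ci.point,
            "ci": [self.ci.lower, self.ci.upper],
            "excludes_zero": self.ci.excludes_zero(),
        }


@dataclass
class AnalysisResult:
    measures: pd.DataFrame
    cells: list[CellResult]
    comparisons: list[ComparisonResult]
    inventories: dict[str, UnitInventory]
    seeds: dict[str, int]
    n_targets: int

    def cell(self, predictor: str, response: str, mode: str = "full") -> CellResult:
        for c in self.cells:
            if (c.predictor, c.response, c.mode) == (predictor, response, mode):
                return c
        raise KeyError((predictor, response, mode))

    def comparison(self, name: str, mode: str) -> ComparisonResult:
        for c in self.comparisons:
            if (c.name, c.mode) == (name, mode):
                return c
        raise KeyError((name, mode))

    def to_dict(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "seeds": self.seeds,
            "cells": [c.to_dict() for c in self.cells],
            "comparisons": [c.to_dict() for c in self.comparisons],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_table(self) -> str:
        """Plain-text summary of all cells and contrasts."""
        lines = [f"{'predictor':16s} {'response':6s} {'mode':8s} "
                 f"{'tau':>8s} {'95% CI':>18s}"]
        for c in self.cells:
            d = c.to_dict()
            if d.get("undefined"):
                lines.append(f"{c.predictor:16s} {c.response:6s} {c.mode:8s} "
                             f"{'undefined':>8s}")
                continue
            ci = d.get("ci")
            ci_s = f"[{ci[0]:+.3f}, {ci[1]:+.3f}]" if ci else ""
            lines.append(f"{c.predictor:16s} {c.response:6s} {c.mode:8s} "
                         f"{d['tau']:+8.3f} {ci_s:>18s}")
        lines.append("")
        lines.append(f"{'contrast (|a|-|b|)':44s} {'mode':8s} {'point':>7s} "
                     f"{'95% CI':>18s} {'sig':>4s}")
        for c in self.comparisons:
            d = c.to_dict()
            lines.append(
                f"{c.name:44s} {c.mode:8s} {d['point']:+7.3f} "
                f"[{d['ci'][0]:+.3f}, {d['ci'][1]:+.3f}] "
                f"{'yes' if d['excludes_zero'] else 'no':>4s}"
            )
        return "\n".join(lines)


def build_measures(
    cds: Corpus,
    ads: Corpus,
    inventories: Mapping[str, UnitInventory],
    aofp: Mapping[str, float],
    rts: Mapping[str, float],
    min_unit_length: int = 2,
) -> pd.DataFrame:
    """Per-target-word measure table over the four-source intersection."""
    targets = select_target_words(cds, ads, aofp, rts)
    words = sorted(targets)
    cols = {
        "freq_cds": word_frequencies(cds, targets),
        "freq_ads": word_frequencies(ads, targets),
        "n_mwus_cds": count_units_per_word(inventories["cbl_cds"], targets, min_unit_length),
        "n_mwus_ads": count_units_per_word(inventories["cbl_ads"], targets, min_unit_length),
        "n_baseline_cds": count_units_per_word(inventories["baseline_cds"], targets, min_unit_length),
        "n_baseline_ads": count_units_per_word(inventories["baseline_ads"], targets, min_unit_length),
        "aofp": dict(aofp),
        "rt": dict(rts),
    }
    df = pd.DataFrame({name: [col[w] for w in words] for name, col in cols.items()},
                      index=pd.Index(words, name="word"))
    return df


def _full_cell(df: pd.DataFrame, predictor: str, response: str,
               reps: int, seed: int) -> CellResult:
    x = df[predictor].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    try:
        tau = kendall_tau_b(x, y)
        ci = bootstrap_ci(lambda a, b: kendall_tau_b(a, b).tau, (x, y),
                          reps=reps, seed=seed)
    except DegenerateRankingError:
        return CellResult(predictor, response, "full", None, None, None)
    return CellResult(predictor, response, "full", None, tau, ci)


def _partial_cell(df: pd.DataFrame, predictor: str, response: str,
                  control: str, reps: int, seed: int) -> CellResult:
    x = df[predictor].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    f = df[control].to_numpy(dtype=float)
    try:
        point = partial_tau_b(x, y, f)
        ci = bootstrap_ci(partial_tau_b, (x, y, f), reps=reps, seed=seed)
    except DegenerateRankingError:
        return CellResult(predictor, response, "partial", control, None, None)
    return CellResult(predictor, response, "partial", control, None, ci,
                      partial_point=float(point))


def run_analysis(
    cds: Corpus,
    ads: Corpus,
    transcripts: TranscriptSet,
    rts: Mapping[str, float],
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the complete correlational analysis; deterministic given config.seed."""
    config = config or PipelineConfig()
    seeds = {
        "baseline_cds": _subseed(config.seed, 1),
        "baseline_ads": _subseed(config.seed, 2),
        "mlu": _subseed(config.seed, 3),
        "bootstrap": _subseed(config.seed, 4),
    }

    cbl_cfg = ChunkerConfig(mode="cbl", threshold_mode=config.threshold_mode)
    inv_cbl_cds, _ = run_cbl(cds, cbl_cfg)
    inv_cbl_ads, _ = run_cbl(ads, cbl_cfg)
    inv_base_cds, _ = run_baseline(
        cds, ChunkerConfig(mode="baseline", seed=seeds["baseline_cds"],
                           baseline_attach_prob=config.baseline_attach_prob))
    inv_base_ads, _ = run_baseline(
        ads, ChunkerConfig(mode="baseline", seed=seeds["baseline_ads"],
                           baseline_attach_prob=config.baseline_attach_prob))
    inventories = {
        "cbl_cds": inv_cbl_cds,
        "cbl_ads": inv_cbl_ads,
        "baseline_cds": inv_base_cds,
        "baseline_ads": inv_base_ads,
    }

    mlus = estimate_mlus(transcripts, reps=config.mlu_reps, seed=seeds["mlu"])
    aofp = assign_aofp(transcripts, mlus).as_mapping()

    df = build_measures(cds, ads, inventories, aofp, rts, config.min_unit_length)

    cells: list[CellResult] = []
    boot_seed = seeds["bootstrap"]
    k = 0
    for response in RESPONSES:
        for predictor in PREDICTORS:
            cells.append(_full_cell(df, predictor, response, config.reps,
                                    _subseed(boot_seed, k)))
            k += 1
            cells.append(_partial_cell(df, predictor, response,
                                       CONTROL[predictor], config.reps,
                                       _subseed(boot_seed, k)))
            k += 1

    comparisons: list[ComparisonResult] = []

    def add_contrast(name: str, analysis: str, mode: str,
                     stat_a, stat_b, cols: list[str]) -> None:
        nonlocal k
        data = [df[c].to_numpy(dtype=float) for c in cols]
        try:
            ci = bootstrap_difference_ci(stat_a, stat_b, data, reps=config.reps,
                                         seed=_subseed(boot_seed, k), absolute=True)
        except DegenerateRankingError:
            k += 1
            return
        k += 1
        comparisons.append(ComparisonResult(name, analysis, mode, ci))

    def tau_of(i: int, j: int):
        return lambda *cols: kendall_tau_b(cols[i], cols[j]).tau

    def ptau_of(i: int, j: int, c: int):
        return lambda *cols: partial_tau_b(cols[i], cols[j], cols[c])

    # register contrasts: for each response, the designated register's
    # predictor against its counterpart from the other register
    register_pairs = [
        ("rt", "freq_ads", "freq_cds"),
        ("rt", "n_mwus_ads", "n_mwus_cds"),
        ("aofp", "freq_cds", "freq_ads"),
        ("aofp", "n_mwus_cds", "n_mwus_ads"),
    ]
    for response, pa, pb in register_pairs:
        name = f"{pa}~{response} vs {pb}~{response}"
        add_contrast(name, "register", "full",
                     tau_of(0, 2), tau_of(1, 2), [pa, pb, response])
        add_contrast(name, "register", "partial",
                     ptau_of(0, 2, 3), ptau_of(1, 2, 4),
                     [pa, pb, response, CONTROL[pa], CONTROL[pb]])

    # chunker vs baseline on the designated response
    baseline_pairs = [
        ("rt", "n_mwus_ads", "n_baseline_ads", "freq_ads"),
        ("aofp", "n_mwus_cds", "n_baseline_cds", "freq_cds"),
    ]
    for response, pa, pb, ctrl in baseline_pairs:
        name = f"{pa}~{response} vs {pb}~{response}"
        add_contrast(name, "baseline", "full",
                     tau_of(0, 2), tau_of(1, 2), [pa, pb, response])
        add_contrast(name, "baseline", "partial",
                     ptau_of(0, 2, 3), ptau_of(1, 2, 3),
                     [pa, pb, response, ctrl])

    # cross-response contrasts: ADS predictor on RT vs CDS counterpart on AoFP
    cross_pairs = [
        ("freq_ads", "freq_cds"),
        ("n_mwus_ads", "n_mwus_cds"),
    ]
    for pa, pb in cross_pairs:
        name = f"{pa}~rt vs {pb}~aofp"
        add_contrast(name, "cross_response", "full",
                     tau_of(0, 2), tau_of(1, 3), [pa, pb, "rt", "aofp"])
        add_contrast(name, "cross_response", "partial",
                     ptau_of(0, 2, 4), ptau_of(1, 3, 5),
                     [pa, pb, "rt", "aofp", CONTROL[pa], CONTROL[pb]])

    return AnalysisResult(
        measures=df,
        cells=cells,
        comparisons=comparisons,
        inventories=inventories,
        seeds=seeds,
        n_targets=len(df),
    )
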