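"""Transcriptional energy cost of mRNA in activated phosphate bonds (~P).

The per-molecule synthesis cost of a transcript is additive over its
nucleotides: each base contributes its biosynthesis cost plus a
polymerization (elongation) charge, and one per-molecule overhead covers
transcription initiation and termination. The 5'UTR, CDS and 3'UTR regions
are costed separately so their contributions to rhythm amplitude can be
compared.

At steady state a pool of E mRNA copies decaying at rate d (per hour) must
be resynthesized at rate E*d, so the ongoing transcriptional power drain is

    steady_state_cost = E * d * per_molecule_cost      [~P per hour]

Expression level stands in for the copy number in arbitrary units; all
downstream use is correlational, so only relative costs matter. The
initiation/termination overhead is charged per synthesis event, i.e. it is
multiplied by the replacement rate as well (configurable in principle by
zeroing ``overhead`` in the cost table).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "CostTable",
    "load_cost_table",
    "counts_from_sequence",
    "region_cost",
    "per_molecule_cost",
    "steady_state_cost",
    "compute_cost_profiles",
    "cost_amplitude_correlations",
]

_BASES = ("A", "C", "G", "U")
_REGION_SUFFIX = {"5utr": "5", "cds": "C", "3utr": "3"}


@dataclass(frozen=True)
class CostTable:
    """Per-base synthesis costs, elongation cost per nt and per-molecule
    initiation/termination overhead, all in ~P."""

    synthesis: dict
    elongation: float
    overhead: float

    def __post_init__(self):
        missing = [b for b in _BASES if b not in self.synthesis]
        if missing:
            raise ValueError(f"cost table missing bases: {missing}")
        if any(v < 0 for v in self.synthesis.values()) \
                or self.elongation < 0 or self.overhead < 0:
            raise ValueError("cost table entries must be non-negative")


def load_cost_table(path=None) -> CostTable:
    """Load a cost table from TOML; default is the table shipped with the
    package (see ``circacost/data/cost_table.toml`` for the key layout)."""
    if path is None:
        text = resources.files("circacost").joinpath("data/cost_table.toml").read_text()
        doc = tomllib.loads(text)
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    return CostTable(synthesis={b: float(doc["synthesis"][b]) for b in _BASES},
                     elongation=float(doc["elongation"]),
                     overhead=float(doc["overhead"]))


def counts_from_sequence(seq: str) -> dict:
    """Base counts from an RNA/DNA sequence; T counts as U, case ignored.

    IUPAC ambiguity codes are rejected with a clear error.
    """
    counts = dict.fromkeys(_BASES, 0)
    for ch in seq.upper():
        if ch == "T":
            ch = "U"
        if ch not in counts:
            raise ValueError(f"unsupported base symbol {ch!r} "
                             "(ambiguity codes are not accepted)")
        counts[ch] += 1
    return counts


def region_cost(base_counts, table: CostTable) -> float:
    """~P to synthesize one region: sum of count * (synthesis + elongation).

    The per-molecule overhead is *not* charged at region level.
    """
    total = 0.0
    for base, count in dict(base_counts).items():
        b = "U" if base.upper() == "T" else base.upper()
        if b not in _BASES:
            raise ValueError(f"unknown base symbol {base!r}")
        if count < 0:
            raise ValueError("base counts must be non-negative")
        total += count * (table.synthesis[b] + table.elongation)
    return total


def _region_counts(row, suffix):
    return {b: row[f"{b.lower()}{suffix}"] for b in _BASES}


def per_molecule_cost(model, table: CostTable) -> dict:
    """Region costs and total per-molecule cost for one transcript model.

    ``model`` is a mapping/Series with the transcript-model columns
    (a5..u5, aC..uC, a3..u3, decay_rate). The total charges the overhead
    once per molecule. A model whose three regions are all empty is
    rejected.
    """
    costs = {region: region_cost(_region_counts(model, sfx), table)
             for region, sfx in _REGION_SUFFIX.items()}
    length = sum(model[f"{b.lower()}{s}"] for b in _BASES
                 for s in _REGION_SUFFIX.values())
    if length == 0:
        raise ValueError("transcript model has no nucleotides in any region")
    return {
        "cost_5utr": costs["5utr"],
        "cost_cds": costs["cds"],
        "cost_3utr": costs["3utr"],
        "per_molecule_total": costs["5utr"] + costs["cds"] + costs["3utr"]
                              + table.overhead,
    }


def steady_state_cost(per_molecule_total, expression_level, decay_rate):
    """~P per hour to maintain the pool: expression * decay * per-molecule."""
    per_molecule_total = np.asarray(per_molecule_total, dtype=float)
    expression_level = np.asarray(expression_level, dtype=float)
    decay_rate = np.asarray(decay_rate, dtype=float)
    if np.any(expression_level < 0):
        raise ValueError("expression level must be non-negative")
    if np.any(decay_rate <= 0):
        raise ValueError("decay rate must be positive")
    out = expression_level * decay_rate * per_molecule_total
    return float(out) if out.ndim == 0 else out


def compute_cost_profiles(models: pd.DataFrame, table: CostTable,
                          expression: pd.Series | None = None) -> pd.DataFrame:
    """Vectorized cost profile per transcript.

    Emits per-molecule region costs and total; when ``expression`` (a
    Series indexed by transcript_id, mean expression per gene) is supplied,
    also the steady-state (copy-number- and decay-weighted) region costs
    ``ss_cost_*`` and the total ``steady_state_cost``.
    """
    out = pd.DataFrame({"transcript_id": models["transcript_id"]})
    per_base = {b: table.synthesis[b] + table.elongation for b in _BASES}
    lengths = np.zeros(len(models))
    for region, sfx in _REGION_SUFFIX.items():
        cost = np.zeros(len(models), dtype=float)
        for b in _BASES:
            col = models[f"{b.lower()}{sfx}"].to_numpy()
            if np.any(col < 0):
                raise ValueError("base counts must be non-negative")
            cost += col * per_base[b]
            lengths += col
        out[f"cost_{region}"] = cost
    if np.any(lengths == 0):
        raise ValueError("transcript model with no nucleotides in any region")
    out["per_molecule_total"] = (out["cost_5utr"] + out["cost_cds"]
                                 + out["cost_3utr"] + table.overhead)
    out["decay_rate"] = models["decay_rate"].to_numpy()
    if expression is not None:
        expr = out["transcript_id"].map(expression).to_numpy(dtype=float)
        if np.any(~np.isfinite(expr)):
            raise ValueError("expression missing for some transcripts")
        rate = expr * out["decay_rate"].to_numpy()
        for region in _REGION_SUFFIX:
            out[f"ss_cost_{region}"] = rate * out[f"cost_{region}"]
        out["expression_level"] = expr
        out["steady_state_cost"] = rate * out["per_molecule_total"]
    return out


def cost_amplitude_correlations(profiles: pd.DataFrame,
                                rhythms: pd.DataFrame) -> pd.DataFrame:
    """Per-region correlation between log steady-state cost and log amplitude.

    Joins cost profiles with rhythm records, keeps cycling genes with
    positive amplitude and positive costs, and reports Pearson r, p and the
    single-predictor R^2 for each region's steady-state cost, plus the
    expression-versus-total-cost correlation (how expensive highly
    expressed rhythmic genes are).
    """
    df = profiles.merge(rhythms, on="transcript_id")
    df = df[df["is_cycling"] & (df["amplitude"] > 0)]
    regions = [f"ss_cost_{r}" for r in _REGION_SUFFIX]
    for col in regions + ["steady_state_cost"]:
        df = df[df[col] > 0]
    if len(df) < 3:
        raise ValueError("fewer than 3 usable cycling genes")
    log_amp = np.log(df["amplitude"].to_numpy())
    rows = []
    for region, col in zip(_REGION_SUFFIX, regions):
        x = np.log(df[col].to_numpy())
        if np.ptp(x) == 0 or np.ptp(log_amp) == 0:
            raise ValueError("degenerate variance in cost or amplitude")
        fit = linregress(x, log_amp)
        rows.append({"predictor": f"cost_{region}", "target": "amplitude",
                     "n": len(df), "pearson_r": fit.rvalue,
                     "p_value": fit.pvalue, "r_squared": fit.rvalue**2})
    fit = linregress(np.log(df["mean_expression"].to_numpy()),
                     np.log(df["steady_state_cost"].to_numpy()))
    rows.append({"predictor": "mean_expression", "target": "steady_state_cost",
                 "n": len(df), "pearson_r": fit.rvalue,
                 "p_value": fit.pvalue, "r_squared": fit.rvalue**2})
    return pd.DataFrame(rows)
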