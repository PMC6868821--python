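"""Tissue-specificity and functional-enrichment controls.

These are the negative controls around the expression-amplitude story:
how many organs each transcript cycles in, whether expression-amplitude
coupling survives controlling for that count (partial correlation), an
internal hypergeometric gene-set enrichment with the standard
fold-enrichment definition (k/n)/(K/N) against a background of all
expressed genes, the relation between a pathway's fold-enrichment and the
mean amplitude of its cycling members (optionally controlling the
pathway's mean expression, which is the planted confounder), and a
two-group amplitude contrast (e.g. housekeeping versus other cycling
genes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr, ranksums

from .rhythm_detection import bh_adjust

__all__ = [
    "cyclic_tissue_number",
    "partial_correlation",
    "hypergeometric_enrichment",
    "enrichment_amplitude_relation",
    "group_amplitude_contrast",
    "tissue_controlled_coupling",
]


def cyclic_tissue_number(organ_rhythms: dict) -> pd.Series:
    """Number of organs in which each transcript is called cycling.

    ``organ_rhythms`` maps organ name to that organ's rhythm-record frame.
    The universe is the union of all transcript ids; transcripts cycling
    nowhere get 0.
    """
    if not organ_rhythms:
        raise ValueError("need at least one organ")
    counts = None
    for df in organ_rhythms.values():
        s = df.set_index("transcript_id")["is_cycling"].astype(int)
        counts = s if counts is None else counts.add(s, fill_value=0)
    return counts.astype(int).rename("cyclic_tissue_number")


def partial_correlation(x, y, z) -> float:
    """First-order partial correlation r_xy.z.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    Raises if z is collinear with x or y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (x.size == y.size == z.size) or x.size < 4:
        raise ValueError("x, y, z must have equal length >= 4")
    for v in (x, y, z):
        if np.ptp(v) == 0:
            raise ValueError("degenerate variance")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("z is collinear with x or y")
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom), -1.0, 1.0))


def hypergeometric_enrichment(cycling, background, genesets: dict,
                              rhythms: pd.DataFrame | None = None) -> pd.DataFrame:
    """Over-representation of each gene set among cycling genes.

    With N background genes, n cycling, K term members in the background
    and k of them cycling: fold_enrichment = (k/n) / (K/N) and p is the
    upper hypergeometric tail P(X >= k); BH adjustment runs across terms.
    Gene sets are intersected with the background before testing and the
    cycling set must be contained in the background. When ``rhythms`` is
    given, each term also carries the mean log2 amplitude and mean log2
    expression of its overlapping cycling genes.
    """
    background = set(background)
    cycling = set(cycling)
    if not background or not cycling:
        raise ValueError("background and cycling sets must be non-empty")
    if not cycling <= background:
        raise ValueError("cycling genes must be a subset of the background")
    N, n = len(background), len(cycling)
    amp = expr = None
    if rhythms is not None:
        cyc = rhythms[rhythms["is_cycling"] & (rhythms["amplitude"] > 0)]
        amp = cyc.set_index("transcript_id")["amplitude"]
        expr = cyc.set_index("transcript_id")["mean_expression"]
    rows = []
    for term, members in genesets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        overlap = in_bg & cycling
        k = len(overlap)
        fold = (k / n) / (K / N) if K else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        row = {"term_id": term, "term_size": K, "overlap": k,
               "fold_enrichment": fold, "p": min(p, 1.0)}
        if amp is not None:
            ids = [g for g in overlap if g in amp.index]
            row["mean_amplitude"] = float(np.log2(amp[ids]).mean()) if ids else np.nan
            row["mean_expression"] = float(np.log2(expr[ids]).mean()) if ids else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def enrichment_amplitude_relation(records: pd.DataFrame, control: str = "none",
                                  alpha: float = 0.05, top_k: int | None = None) -> dict:
    """Correlate pathway fold-enrichment with mean member amplitude.

    Restricted to significant terms (adj_p < alpha), optionally further to
    the ``top_k`` most enriched. ``control="expression"`` additionally
    reports the partial correlation controlling each term's mean log
    expression (per-term mean of member log expression). Fewer than 3
    usable terms yields an underpowered report without a correlation.
    """
    df = records[(records["adj_p"] < alpha) & records["mean_amplitude"].notna()]
    if top_k is not None:
        df = df.nlargest(top_k, "fold_enrichment")
    report = {"n_terms": len(df), "alpha": alpha, "control": control,
              "underpowered": len(df) < 3}
    if report["underpowered"]:
        return report
    r, p = pearsonr(df["fold_enrichment"], df["mean_amplitude"])
    report.update({"r": float(r), "p": float(p)})
    if control == "expression":
        report["partial_r"] = partial_correlation(
            df["fold_enrichment"], df["mean_amplitude"], df["mean_expression"])
    elif control != "none":
        raise ValueError("control must be 'none' or 'expression'")
    return report


def group_amplitude_contrast(group_a, group_b, rhythms: pd.DataFrame) -> dict:
    """Mean log-amplitude difference (A - B) among cycling genes with a
    two-sided Wilcoxon rank-sum p."""
    cyc = rhythms[rhythms["is_cycling"] & (rhythms["amplitude"] > 0)]
    amp = cyc.set_index("transcript_id")["amplitude"]
    a = np.log(amp[amp.index.intersection(set(group_a))].to_numpy())
    b = np.log(amp[amp.index.intersection(set(group_b))].to_numpy())
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 cycling members")
    stat, p = ranksums(a, b)
    return {"n_a": int(a.size), "n_b": int(b.size),
            "mean_log_amplitude_diff": float(a.mean() - b.mean()),
            "statistic": float(stat), "p": float(p)}


def tissue_controlled_coupling(organ_rhythms: dict) -> pd.DataFrame:
    """Per-organ expression-amplitude correlation before and after
    controlling for the cyclic tissue number.

    For each organ's cycling genes: raw Pearson r between log mean
    expression and log amplitude, and the partial r given the number of
    organs in which the gene cycles.
    """
    tissue_n = cyclic_tissue_number(organ_rhythms)
    rows = []
    for organ, df in organ_rhythms.items():
        cyc = df[df["is_cycling"] & (df["amplitude"] > 0)]
        if len(cyc) < 4:
            continue
        x = np.log(cyc["mean_expression"].to_numpy())
        y = np.log(cyc["amplitude"].to_numpy())
        z = tissue_n[cyc["transcript_id"]].to_numpy(dtype=float)
        raw = float(np.corrcoef(x, y)[0, 1])
        partial = partial_correlation(x, y, z) if np.ptp(z) > 0 else raw
        rows.append({"organ": organ, "n": len(cyc), "raw_r": raw,
                     "partial_r_tissue_number": partial})
    return pd.DataFrame(rows)
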