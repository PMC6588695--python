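"""Metabolite-to-gene linking, pathway enrichment, and expression-shift tests.

Peaks are linked to genes through their putative compound annotations
(every matched compound contributes all of its directly linked enzymes);
pathway overrepresentation is an upper-tail hypergeometric test against the
background of genes linked to all detected peaks, BH-corrected across
pathways. Pathway-set overlaps use one-sided Fisher exact tests, and the
expression-shift comparison contrasts per-peak proportions of
differentially expressed linked genes with a two-sample KS test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, ArgumentError, ValidationError
from .differential import bh_adjust


@dataclass
class PathwayAnnotation:
    """Static metabolite→gene and gene→pathway mapping tables."""

    metabolite_to_genes: dict[str, set[str]]
    gene_to_pathways: dict[str, set[str]]
    pathway_names: dict[str, str]

    @classmethod
    def from_tables(
        cls, met_gene: pd.DataFrame, gene_pathway: pd.DataFrame
    ) -> "PathwayAnnotation":
        """Build from CSV-style frames (compound_id, gene_id) and
        (gene_id, pathway_id[, pathway_name])."""
        m2g: dict[str, set[str]] = {}
        for cid, gid in zip(met_gene["compound_id"], met_gene["gene_id"]):
            m2g.setdefault(str(cid), set()).add(str(gid))
        g2p: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for _, row in gene_pathway.iterrows():
            g2p.setdefault(str(row["gene_id"]), set()).add(str(row["pathway_id"]))
            if "pathway_name" in gene_pathway.columns:
                names[str(row["pathway_id"])] = str(row["pathway_name"])
        return cls(m2g, g2p, names)

    def pathways(self) -> set[str]:
        out: set[str] = set()
        for ps in self.gene_to_pathways.values():
            out |= ps
        return out

    def pathway_genes(self, pathway_id: str) -> set[str]:
        return {
            g for g, ps in self.gene_to_pathways.items() if pathway_id in ps
        }


@dataclass
class ExpressionConfig:
    log2fc_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ArgumentError("log2fc_threshold must be > 0")


def link_genes(
    peak_ids: list[str],
    annotations: pd.DataFrame,
    pathway_annotation: PathwayAnnotation,
    background_peak_ids: list[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Union of genes linked to the given peaks via compound annotation.

    Returns (selected genes, background genes), the background being the
    same union over all detected peaks (``background_peak_ids``, defaulting
    to every peak present in the annotation table).
    """
    by_peak = annotations.groupby("peak_id")["compound_id"].agg(set)

    def genes_for(peaks: list[str]) -> set[str]:
        out: set[str] = set()
        n_unannotated = 0
        for pid in peaks:
            compounds = by_peak.get(pid, set())
            if not compounds:
                n_unannotated += 1
                continue
            for cid in compounds:
                out |= pathway_annotation.metabolite_to_genes.get(cid, set())
        if n_unannotated:
            warnings.warn(
                f"{n_unannotated} peak(s) contributed no genes (unannotated)"
            )
        return out

    selected = genes_for(list(peak_ids))
    if background_peak_ids is None:
        background_peak_ids = list(by_peak.index)
    background = genes_for(list(background_peak_ids))
    return selected, background | selected


def hypergeom_enrichment(
    selected: set[str],
    background: set[str],
    pathway_annotation: PathwayAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric pathway overrepresentation, BH-corrected.

    For each pathway with at least one background gene: the overlap between
    ``selected`` and pathway∩background is tested against a draw of
    |selected| genes from the background.
    """
    if not selected <= background:
        raise ValidationError("selected genes must be a subset of the background")
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for pw in sorted(pathway_annotation.pathways()):
        pw_genes = pathway_annotation.pathway_genes(pw) & background
        if not pw_genes:
            continue
        overlap = len(pw_genes & selected)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(pw_genes), n_sel))
        rows.append(
            (
                pw,
                pathway_annotation.pathway_names.get(pw, pw),
                overlap,
                n_sel,
                n_bg,
                len(pw_genes),
                p,
            )
        )
    if not rows:
        raise AnalysisError("no pathway intersects the background")
    res = pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "pathway_name", "overlap_count",
            "selected_gene_count", "background_gene_count",
            "pathway_gene_count", "p",
        ],
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["q"] <= alpha
    return res.sort_values(["q", "p", "pathway_id"], kind="stable").reset_index(
        drop=True
    )


def fisher_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[np.ndarray, float]:
    """One-sided (enrichment) Fisher exact test for two set memberships."""
    if not universe:
        raise ArgumentError("universe must be non-empty")
    if not (set_a <= universe and set_b <= universe):
        raise ValidationError("A and B must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe - set_a - set_b)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return table, float(p)


def expression_shift_test(
    asd_peak_ids: list[str],
    other_peak_ids: list[str],
    annotations: pd.DataFrame,
    pathway_annotation: PathwayAnnotation,
    gene_log2fc: dict[str, float],
    config: ExpressionConfig | None = None,
) -> tuple[pd.Series, pd.Series, float, float]:
    """Compare expression-shift proportions of ASD vs other peaks' genes.

    Per peak: the proportion of its linked genes (with fold-change data)
    whose |log2FC| exceeds the threshold. Returns (ASD proportions, other
    proportions, KS statistic, p) from a two-sample KS test.
    """
    if config is None:
        config = ExpressionConfig()
    by_peak = annotations.groupby("peak_id")["compound_id"].agg(set)

    def proportions(peaks: list[str]) -> pd.Series:
        vals = {}
        for pid in peaks:
            genes: set[str] = set()
            for cid in by_peak.get(pid, set()):
                genes |= pathway_annotation.metabolite_to_genes.get(cid, set())
            genes = {g for g in genes if g in gene_log2fc}
            if not genes:
                continue
            hits = sum(
                1 for g in genes if abs(gene_log2fc[g]) > config.log2fc_threshold
            )
            vals[pid] = hits / len(genes)
        return pd.Series(vals, dtype=float)

    prop_asd = proportions(list(asd_peak_ids))
    prop_other = proportions(list(other_peak_ids))
    if prop_asd.empty or prop_other.empty:
        raise AnalysisError("all peaks in one group are unlinked to expression data")
    ks = stats.ks_2samp(prop_asd.to_numpy(), prop_other.to_numpy())
    return prop_asd, prop_other, float(ks.statistic), float(ks.pvalue)
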