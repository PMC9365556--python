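"""Ranked CpG and gene lists from PC loadings, for preranked enrichment.

Each PC's CpGs are scored by |loading| x a standard deviation and the top
fraction is kept.  Two sd conventions exist in practice and both are
provided: ``cpg_sd`` (default) multiplies each loading by the sd of that
CpG's betas in a reference cohort; ``pc_sd`` multiplies by the sd of the
projected PC score — a single scalar, so the ranking reduces to |loading|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix
from .pc import PCModel, project


@dataclass
class RankedList:
    """Ordered (id, score) pairs for one PC, scores non-increasing."""

    pc_index: int
    entries: list[tuple[str, float]]
    top_fraction: float
    mode: str

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in ranked list")
        scores = [s for _, s in self.entries]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]


def rank_cpgs(
    model: PCModel,
    pc_index: int,
    reference: BetaMatrix | dict[str, float] | pd.Series,
    mode: str = "cpg_sd",
    top_fraction: float = 0.10,
) -> RankedList:
    """Rank the model's CpGs for one PC by |loading| x sd, keep the top fraction.

    ``reference`` is the cohort (or a precomputed probe -> sd mapping) whose
    variability weights the loadings in ``cpg_sd`` mode; in ``pc_sd`` mode
    it is the cohort on which the projected score sd is measured.  Ties are
    broken lexicographically by probe id; the list is truncated to
    ``ceil(top_fraction * n_probes)`` entries.
    """
    if mode not in ("cpg_sd", "pc_sd"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (1 <= pc_index <= model.n_components):
        raise ValueError(f"pc_index must lie in 1..{model.n_components}")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    loadings = np.abs(model.rotation[:, pc_index - 1])
    probe_ids = np.array(model.probe_ids)
    if mode == "cpg_sd":
        if isinstance(reference, BetaMatrix):
            frame = reference.to_frame()
            missing = [p for p in model.probe_ids if p not in frame.columns]
            if missing:
                raise ValueError(f"reference lacks {len(missing)} model probes")
            sds = frame[model.probe_ids].std(ddof=1).to_numpy()
        else:
            sds = pd.Series(reference, dtype=float).reindex(model.probe_ids).to_numpy()
            if np.isnan(sds).any():
                raise ValueError("sd mapping does not cover all model probes")
        zero = sds <= 0
        if zero.any():
            warnings.warn(f"dropping {int(zero.sum())} zero-variance reference probes")
        keep = ~zero
        scores = loadings[keep] * sds[keep]
        probe_ids = probe_ids[keep]
    else:
        if isinstance(reference, BetaMatrix):
            pc_scores = project(model, reference).scores[:, pc_index - 1]
            scalar_sd = float(np.std(pc_scores, ddof=1))
        else:
            scalar_sd = float(pd.Series(reference, dtype=float).iloc[0]) \
                if not np.isscalar(reference) else float(reference)
        scores = loadings * scalar_sd
    order = np.lexsort((probe_ids, -scores))
    n_keep = int(np.ceil(top_fraction * len(model.probe_ids)))
    order = order[:n_keep]
    entries = [(str(probe_ids[i]), float(scores[i])) for i in order]
    return RankedList(pc_index, entries, top_fraction, mode)


def map_to_genes(ranked: RankedList, annotation: pd.DataFrame) -> list[tuple[str, float]]:
    """Map ranked CpGs to genes: unannotated probes dropped, genes deduplicated
    to their first (highest-ranked) occurrence, order otherwise preserved."""
    gene_of = annotation.set_index("probe_id")["gene"]
    out, seen = [], set()
    for probe, score in ranked.entries:
        gene = str(gene_of.get(probe, ""))
        if not gene or gene in seen:
            continue
        seen.add(gene)
        out.append((gene, score))
    if not out:
        warnings.warn("no ranked probe maps to an annotated gene")
    return out


def background_genes(annotation: pd.DataFrame) -> list[str]:
    """Sorted unique non-empty gene symbols across the whole annotation."""
    genes = annotation["gene"].astype(str)
    return sorted({g for g in genes if g})


def write_ranked_list(entries: RankedList | list, path) -> None:
    """Write a two-column tab-separated ranked list (id, score), descending."""
    if isinstance(entries, RankedList):
        entries = entries.entries
    if not entries:
        warnings.warn(f"writing empty ranked list to {path}")
    with open(path, "w") as fh:
        fh.write("id\tscore\n")
        for item in entries:
            if isinstance(item, tuple):
                fh.write(f"{item[0]}\t{item[1]!r}\n")
            else:
                fh.write(f"{item}\n")


def read_ranked_list(path) -> list[tuple[str, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise ValueError(f"not a ranked-list file: {path}")
        for line in fh:
            name, score = line.rstrip("\n").split("\t")
            out.append((name, float(score)))
    return out
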