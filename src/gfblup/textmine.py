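"""Gene-symbol extraction from abstracts and mapping mined genes to SNP panels.

The mining rule is deliberately simple: tokens consisting only of capital
letters and digits (at least two characters, at least one letter) are
candidate symbols; of those, only tokens found in a curated gene-symbol
lexicon are kept.  The all-caps filter is what screens out ordinary words
that collide with gene symbols in lowercase prose ("impact", "pigs").

SNP panels are then partitioned by mined genes: the feature set holds SNPs
inside a mined gene's interval and, optionally, SNPs in intergenic intervals
flanked by a mined gene on either side; the complement set holds the rest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import (AbstractCorpus, GeneAnnotation, GeneLexicon, GenotypePanel,
                 SNPPartition)

logger = logging.getLogger(__name__)

# Tokens split on any non-alphanumeric character (so "IGF-1" -> IGF, 1);
# a kept token is >=2 chars of [A-Z0-9] with at least one letter.
_SPLIT = re.compile(r"[^A-Za-z0-9]+")
_CAPS = re.compile(r"^(?=.*[A-Z])[A-Z0-9]{2,}$")


@dataclass
class MinedGeneSet:
    """Symbol -> occurrence frequency with per-symbol document provenance."""

    trait: str
    frequencies: dict
    provenance: dict = field(default_factory=dict)  # symbol -> set of doc ids

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.frequencies.values()):
            raise ParameterError("mined frequencies must be positive")

    @property
    def symbols(self) -> set:
        return set(self.frequencies)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["symbol", "freq"])


def filter_tokens(text: str) -> list:
    """All-caps/digit tokens of ``text`` in document order, with repeats.

    Leading/trailing punctuation is stripped by splitting on any
    non-alphanumeric character; survivors must be >=2 characters, all
    uppercase letters or digits, with at least one letter.
    """
    return [t for t in _SPLIT.split(text) if t and _CAPS.match(t)]


def mine_genes(corpus: AbstractCorpus, lexicon: GeneLexicon,
               count: str = "occurrences", trait: str = "") -> MinedGeneSet:
    """Count lexicon symbols across all titles and abstracts of ``corpus``.

    ``count="occurrences"`` (default) counts every token hit;
    ``count="articles"`` counts distinct documents mentioning the symbol.
    Alias hits are attributed to their canonical symbol.  Token matching is
    case-sensitive: the all-caps filter runs first, so "Cast" never matches.
    """
    if not lexicon.symbols:
        raise ParameterError("lexicon is empty")
    if count not in ("occurrences", "articles"):
        raise ParameterError("count must be 'occurrences' or 'articles'")
    freqs: dict = {}
    prov: dict = {}
    for rec in corpus:
        doc_syms = set()
        for token in filter_tokens(rec["title"] + " " + rec["abstract"]):
            sym = lexicon.resolve(token)
            if sym is None:
                continue
            if count == "occurrences":
                freqs[sym] = freqs.get(sym, 0) + 1
            else:
                doc_syms.add(sym)
            prov.setdefault(sym, set()).add(rec["id"])
        for sym in doc_syms:
            freqs[sym] = freqs.get(sym, 0) + 1
    return MinedGeneSet(trait, freqs, prov)


def top_frequency_table(mined: MinedGeneSet, k: int) -> pd.DataFrame:
    """Top-k symbols by descending frequency, ties broken alphabetically."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return mined.to_frame().head(k).reset_index(drop=True)


def select_snps(mined: MinedGeneSet, annotation: GeneAnnotation,
                panel: GenotypePanel, include_intergenic: bool = True,
                flank_cap_bp: int | None = None) -> SNPPartition:
    """Partition the panel's SNPs into feature (tm) and complement (exp) sets.

    A SNP is in the feature set if its position lies inside a mined gene's
    [start, end]; with ``include_intergenic``, also if it lies in an
    intergenic interval whose nearest flanking gene on either side is mined
    (optionally within ``flank_cap_bp`` of that gene).  Mined genes absent
    from the annotation are skipped with a warning.
    """
    ann = annotation.table
    missing = mined.symbols - set(ann["symbol"])
    if missing:
        logger.warning("mined genes absent from annotation, skipped: %s",
                       sorted(missing)[:10])
    mined_syms = mined.symbols & set(ann["symbol"])

    tm_mask = np.zeros(panel.n_snps, dtype=bool)
    pos_all = panel.snps["pos"].to_numpy()
    for chrom in panel.chromosomes:
        snp_idx = panel.chrom_indices(chrom)
        pos = pos_all[snp_idx]
        genes = ann[ann["chrom"] == chrom].sort_values("start")
        if genes.empty:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        is_mined = genes["symbol"].isin(mined_syms).to_numpy()

        in_gene = np.zeros(pos.size, dtype=bool)
        in_mined_gene = np.zeros(pos.size, dtype=bool)
        for s, e, mnd in zip(starts, ends, is_mined):
            inside = (pos >= s) & (pos <= e)
            in_gene |= inside
            if mnd:
                in_mined_gene |= inside
        tm_mask[snp_idx[in_mined_gene]] = True

        if include_intergenic and is_mined.any():
            # Nearest flanking genes of each intergenic SNP: the gene with
            # the largest end <= pos (left) and smallest start >= pos (right).
            order_e = np.argsort(ends, kind="stable")
            ends_sorted = ends[order_e]
            left = np.searchsorted(ends_sorted, pos, side="right") - 1
            order_s = np.argsort(starts, kind="stable")
            starts_sorted = starts[order_s]
            right = np.searchsorted(starts_sorted, pos, side="left")
            for j in np.flatnonzero(~in_gene):
                near_mined = False
                if left[j] >= 0:
                    gi = order_e[left[j]]
                    if is_mined[gi] and (flank_cap_bp is None
                                         or pos[j] - ends[gi] <= flank_cap_bp):
                        near_mined = True
                if not near_mined and right[j] < starts.size:
                    gi = order_s[right[j]]
                    if is_mined[gi] and (flank_cap_bp is None
                                         or starts[gi] - pos[j] <= flank_cap_bp):
                        near_mined = True
                if near_mined:
                    tm_mask[snp_idx[j]] = True

    return SNPPartition(panel.n_snps, tm=np.flatnonzero(tm_mask))
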