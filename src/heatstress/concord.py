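"""Gene-protein concordance classification.

Differentially expressed proteins are mapped to transcripts via a
user-supplied protein -> gene-symbol table and each pair is placed in one of
four categories mirroring the quadrant plots of a paired omics comparison:

* ``both_significant`` -- |protein FC| >= 1.3 and |gene FC| >= 2 ("red squares")
* ``protein_only_mapped`` -- significant protein whose mapped gene is below
  the gene threshold ("blue diamonds")
* ``gene_unmapped_significant`` -- significant gene without a significant
  mapped protein partner ("green triangles", plotted on the gene axis)
* ``protein_unmapped_significant`` -- significant protein with no gene
  mapping or no measured gene ("purple triangles", on the protein axis)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from heatstress.util import ConfigurationError

BOTH = "both_significant"
PROTEIN_ONLY_MAPPED = "protein_only_mapped"
GENE_UNMAPPED = "gene_unmapped_significant"
PROTEIN_UNMAPPED = "protein_unmapped_significant"


def map_and_classify(
    gene_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    mapping: pd.DataFrame,
    gene_fc_threshold: float = 2.0,
    protein_fc_threshold: float = 1.3,
) -> pd.DataFrame:
    """Classify gene-protein pairs into concordance categories.

    ``gene_table`` needs columns ``gene_symbol`` and ``fold_change`` (one row
    per probe; multiple probes per symbol are collapsed to the probe of
    maximal |FC|); ``protein_table`` is indexed by protein id with a
    ``fold_change`` column; ``mapping`` has columns ``protein`` and
    ``gene_symbol`` (case-insensitive match). One output row per emitted
    pair, with ``concordant_direction`` true when both fold changes share a
    sign.
    """
    for col in ("gene_symbol", "fold_change"):
        if col not in gene_table.columns:
            raise ConfigurationError(f"gene table missing column {col!r}")
    if "fold_change" not in protein_table.columns:
        raise ConfigurationError("protein table missing column 'fold_change'")
    if mapping.empty or not {"protein", "gene_symbol"} <= set(mapping.columns):
        raise ConfigurationError("mapping must have protein and gene_symbol columns")

    genes = gene_table.copy()
    genes["_symbol"] = genes["gene_symbol"].astype(str).str.lower()
    best = genes.loc[
        genes.groupby("_symbol")["fold_change"].apply(lambda s: s.abs().idxmax())
    ].set_index("_symbol")

    protein_to_gene = {
        str(p): str(g).lower()
        for p, g in zip(mapping["protein"], mapping["gene_symbol"])
    }

    rows = []
    paired_symbols: set[str] = set()
    for protein, prow in protein_table.iterrows():
        pfc = float(prow["fold_change"])
        if abs(pfc) < protein_fc_threshold:
            continue  # sub-threshold proteins are never plotted on their own
        symbol = protein_to_gene.get(str(protein))
        if symbol is None or symbol not in best.index:
            rows.append(
                {
                    "protein": protein,
                    "gene_symbol": symbol,
                    "protein_fc": pfc,
                    "gene_fc": np.nan,
                    "category": PROTEIN_UNMAPPED,
                    "concordant_direction": False,
                }
            )
            continue
        gfc = float(best.loc[symbol, "fold_change"])
        category = BOTH if abs(gfc) >= gene_fc_threshold else PROTEIN_ONLY_MAPPED
        if category == BOTH:
            paired_symbols.add(symbol)
        rows.append(
            {
                "protein": protein,
                "gene_symbol": best.loc[symbol, "gene_symbol"],
                "protein_fc": pfc,
                "gene_fc": gfc,
                "category": category,
                "concordant_direction": bool(np.sign(gfc) == np.sign(pfc)),
            }
        )

    sig_genes = best[best["fold_change"].abs() >= gene_fc_threshold]
    for symbol, grow in sig_genes.iterrows():
        if symbol in paired_symbols:
            continue
        rows.append(
            {
                "protein": None,
                "gene_symbol": grow["gene_symbol"],
                "protein_fc": np.nan,
                "gene_fc": float(grow["fold_change"]),
                "category": GENE_UNMAPPED,
                "concordant_direction": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "gene_symbol",
            "protein_fc",
            "gene_fc",
            "category",
            "concordant_direction",
        ],
    )


def category_counts(pairs: pd.DataFrame) -> pd.Series:
    """Summary counts per concordance category (the figures' legend counts)."""
    counts = pairs["category"].value_counts()
    return counts.reindex(
        [BOTH, PROTEIN_ONLY_MAPPED, GENE_UNMAPPED, PROTEIN_UNMAPPED], fill_value=0
    )
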