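"""miRNA-target lookup with arm-name disambiguation.

Target databases frequently record the hairpin name (``mir-22``) where
the expression matrix carries mature arms (``mir-22-3p``/``-5p``), and
mix ``miR``/``mir`` capitalisation.  Lookup resolves database names onto
expression-matrix IDs: exact match first, otherwise both arm-suffixed
variants.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

ARM_SUFFIXES = ("-3p", "-5p")


def expand_name(name: str, known_ids: set[str]) -> set[str]:
    """Resolve a database miRNA name onto known expression IDs.

    Exact members of ``known_ids`` resolve to themselves; otherwise the
    ``-3p`` and ``-5p`` arm variants are tried and whichever exist are
    returned.  An empty set marks the name unresolvable.  Matching is
    case-sensitive.
    """
    if name in known_ids:
        return {name}
    return {name + suffix for suffix in ARM_SUFFIXES if name + suffix in known_ids}


def _canonicalize(name: str) -> str:
    # databases write hsa-miR-..., expression files hsa-mir-...
    return name.replace("miR", "mir")


def lookup_targets(
    seed_mirnas: list[str],
    db: pd.DataFrame,
    known_gene_ids: set[str],
) -> pd.DataFrame:
    """Collect target interactions of the seed miRNAs from a database.

    ``db`` has columns (mirna_name, gene_id).  Each record whose
    (capitalisation-canonicalised, arm-expanded) name resolves to a seed
    miRNA yields one interaction per resolved ID, deduplicated on
    (mirna_id, gene_id).  Genes absent from ``known_gene_ids`` (the
    expression universe) are retained but flagged, since they may still
    seed the PPI expansion.

    Returns columns: mirna_id, gene_id, source_name, in_gene_universe.
    """
    seed_set = set(seed_mirnas)
    n_canon = sum(1 for name in db["mirna_name"] if _canonicalize(name) != name)
    if n_canon:
        logger.info("canonicalised capitalisation of %d database names", n_canon)

    rows = []
    for name, gene in zip(db["mirna_name"], db["gene_id"]):
        for resolved in sorted(expand_name(_canonicalize(name), seed_set)):
            rows.append(
                {
                    "mirna_id": resolved,
                    "gene_id": gene,
                    "source_name": name,
                    "in_gene_universe": gene in known_gene_ids,
                }
            )
    result = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "source_name", "in_gene_universe"]
    )
    result = result.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
    return result.reset_index(drop=True)
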