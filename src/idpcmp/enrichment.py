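"""Single-organism GO term enrichment of a disordered-protein set.

Re-implementation of the chart-style enrichment workflow popularized by
DAVID: for each GO term the overlap between a study set (here, typically the
proteins with at least one long disordered window) and the proteome
background is scored with a one-sided hypergeometric tail (Fisher) or its
conservative EASE variant (one study hit removed before summing the tail),
adjusted with Benjamini–Hochberg, and filtered at p_adj <= 0.05 with a
minimum of 2 study hits per term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .class_comparison import bh_adjust
from .errors import ConfigError, DataError
from .go_ontology import AnnotationSet

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COUNT = 2


@dataclass
class EnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    background_hits: int
    background_size: int
    p_raw: float
    p_adj: float
    fold_enrichment: float


def _tail_p(k: int, big_n: int, big_k: int, n: int, method: str) -> float:
    """One-sided over-representation p-value P(X >= k).

    ``ease`` removes one study hit (floored at zero) before taking the tail,
    which penalizes terms supported by very few proteins.
    """
    if method == "ease":
        k = max(k - 1, 0)
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def term_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationSet,
    method: str = "fisher",
    background_mode: str = "annotated",
) -> list[EnrichmentResult]:
    """Score every term with at least one study hit for over-representation.

    *study* must be a subset of *background*.  ``background_mode="annotated"``
    (default) restricts the universe to background proteins carrying at least
    one annotation, mirroring chart tools that ignore unannotated genes;
    ``"all"`` uses the full background.  Results are sorted by raw p-value,
    then term id; BH adjustment spans all tested terms.
    """
    if method not in ("fisher", "ease"):
        raise ConfigError(f"method must be 'fisher' or 'ease', got {method!r}")
    if background_mode not in ("annotated", "all"):
        raise ConfigError(
            f"background_mode must be 'annotated' or 'all', got {background_mode!r}"
        )
    if not annotations.expanded:
        raise DataError("term_enrichment requires an expanded annotation set")
    study_set = set(study)
    background_set = set(background)
    if not study_set <= background_set:
        extra = sorted(study_set - background_set)[:5]
        raise DataError(f"study set is not a subset of the background: {extra}")
    if background_mode == "annotated":
        background_set = {
            p for p in background_set if annotations.prot2terms.get(p)
        }
        study_set &= background_set
    big_n = len(background_set)
    n = len(study_set)
    results: list[EnrichmentResult] = []
    for term_id, prots in annotations.term2prots.items():
        big_k = len(prots & background_set)
        k = len(prots & study_set)
        if k == 0 or big_k == 0:
            continue
        p = _tail_p(k, big_n, big_k, n, method)
        expected = big_k * n / big_n if big_n else 0.0
        results.append(
            EnrichmentResult(
                term_id=term_id,
                study_hits=k,
                study_size=n,
                background_hits=big_k,
                background_size=big_n,
                p_raw=p,
                p_adj=1.0,  # filled below
                fold_enrichment=(k / expected) if expected else float("inf"),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    for res, padj in zip(results, bh_adjust([r.p_raw for r in results])):
        res.p_adj = float(padj)
    return results


def filter_enrichment(
    results: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[EnrichmentResult]:
    """Keep terms with p_adj <= alpha (inclusive) and >= min_count study hits."""
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    return [
        r for r in results if r.p_adj <= alpha and r.study_hits >= min_count
    ]
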