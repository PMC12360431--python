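"""Reporting arithmetic and summary-table assembly.

The percentage conventions mirror the style of published comparative
transcriptomics tables: one decimal for proportions quoted with decimals,
nearest integer for synchrony percents.
"""

from __future__ import annotations


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """100 * part / whole, rounded to ``ndigits`` decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / whole, ndigits)


def same_pattern_summary(diagonal_counts, n_pairs: int) -> dict:
    """Trace and same-archetype percent of a cluster-overlap diagonal."""
    trace = int(sum(diagonal_counts))
    return {
        "trace": trace,
        "n_pairs": int(n_pairs),
        "percent_same": percentage(trace, n_pairs, 1),
    }


def synchrony_summary(same_by_stage: dict[str, int], n_asynchronous: int) -> dict:
    """Integer same-stage percent from per-stage same counts and async count."""
    n_same = int(sum(same_by_stage.values()))
    total = n_same + int(n_asynchronous)
    return {
        "n_same": n_same,
        "n_asynchronous": int(n_asynchronous),
        "total": total,
        "percent_same": int(round(100.0 * n_same / total)) if total else 0,
    }


def coding_percent(n_transcripts: int, n_noncoding: int, ndigits: int = 2) -> float:
    """Percent of coding transcripts given total and noncoding counts."""
    return percentage(n_transcripts - n_noncoding, n_transcripts, ndigits)


def cluster_share_percent(n_in_cluster: int, n_degs: int, ndigits: int = 2) -> float:
    """Percent of a species' DEGs falling in one coexpression cluster."""
    return percentage(n_in_cluster, n_degs, ndigits)
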