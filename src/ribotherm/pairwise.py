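"""Comparison of two equal-length sequences' temperature sensitivity.

Significant positions are classified per elevated temperature as shared
(significant in both sequences) or sequence-specific (one sequence only).
A cluster is sequence-specific when its [start, end] span shares no
position with any cluster span of the other sequence; overlap by a single
position already disqualifies it. Onset is the lowest elevated temperature
at which a position (or any member of a cluster) is first significant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import Cluster
from .scan import SignificantPositions


@dataclass(frozen=True)
class ComparisonResult:
    """Position- and cluster-level comparison of sequences A and B."""

    temperatures: tuple[int, ...]
    shared_positions: dict[int, frozenset[int]]
    specific_positions_a: dict[int, frozenset[int]]
    specific_positions_b: dict[int, frozenset[int]]
    specific_clusters_a: tuple[Cluster, ...] = ()
    specific_clusters_b: tuple[Cluster, ...] = ()


def classify_positions(
    sig_a: SignificantPositions, sig_b: SignificantPositions
) -> ComparisonResult:
    """Split significant positions into shared and sequence-specific sets."""
    if sig_a.temperatures != sig_b.temperatures:
        raise ValueError("sequences were scanned over different temperature ranges")
    if sig_a.flags.shape != sig_b.flags.shape:
        raise ValueError("sequences have different lengths")
    shared, spec_a, spec_b = {}, {}, {}
    for t in sig_a.temperatures:
        a, b = sig_a.positions_at(t), sig_b.positions_at(t)
        shared[t] = a & b
        spec_a[t] = a - b
        spec_b[t] = b - a
    return ComparisonResult(
        temperatures=sig_a.temperatures,
        shared_positions=shared,
        specific_positions_a=spec_a,
        specific_positions_b=spec_b,
    )


def specific_clusters(
    clusters_a: list[Cluster], clusters_b: list[Cluster]
) -> tuple[list[Cluster], list[Cluster]]:
    """Clusters whose span overlaps no cluster span of the other sequence."""
    spec_a = [c for c in clusters_a if not any(c.overlaps(d) for d in clusters_b)]
    spec_b = [c for c in clusters_b if not any(c.overlaps(d) for d in clusters_a)]
    return spec_a, spec_b


def onset_temperature(sig: SignificantPositions, position: int) -> int | None:
    """Lowest elevated temperature at which ``position`` is significant."""
    col = position - 1
    if col < 0 or col >= sig.flags.shape[1]:
        raise ValueError(f"position {position} outside sequence")
    for r, t in enumerate(sig.temperatures):
        if sig.flags[r, col]:
            return t
    return None


def cluster_onset(sig: SignificantPositions, cluster: Cluster) -> int | None:
    """Minimum onset over the cluster's member positions."""
    onsets = [onset_temperature(sig, p) for p in cluster.members]
    onsets = [t for t in onsets if t is not None]
    return min(onsets) if onsets else None


# ---------------------------------------------------------------------------
# Annotated comparison rendering
# ---------------------------------------------------------------------------

def _ruler(length: int) -> str:
    marks = [" "] * length
    for p in range(10, length + 1, 10):
        label = str(p)
        start = p - len(label)
        marks[start:p] = list(label)
    return "".join(marks)


def _mark_line(residues: str, shared: frozenset[int], specific: frozenset[int]) -> str:
    """Annotation row: '*' shared, 'o' sequence-specific, '.' otherwise."""
    out = []
    for i in range(1, len(residues) + 1):
        out.append("*" if i in shared else "o" if i in specific else ".")
    return "".join(out)


def render_comparison_text(
    seq_a: str,
    seq_b: str,
    comparison: ComparisonResult,
    id_a: str = "seq_a",
    id_b: str = "seq_b",
    width: int = 80,
) -> str:
    """Plain-text layout of the per-temperature comparison.

    One block per elevated temperature: sequence A with its annotation
    row, a match line ('|' match, '-' substitution), then sequence B and
    its annotation. '*' marks positions significant in both sequences,
    'o' positions significant in that sequence only.
    """
    n = len(seq_a)
    match = "".join("|" if a == b else "-" for a, b in zip(seq_a, seq_b))
    ruler = _ruler(n)
    blocks = []
    for t in comparison.temperatures:
        rows_a = _mark_line(seq_a, comparison.shared_positions[t], comparison.specific_positions_a[t])
        rows_b = _mark_line(seq_b, comparison.shared_positions[t], comparison.specific_positions_b[t])
        lines = [f"# elevated temperature {t} C  ({id_a} vs {id_b})"]
        for s in range(0, n, width):
            e = min(s + width, n)
            lines += [
                "  " + ruler[s:e],
                "A " + seq_a[s:e],
                "  " + rows_a[s:e],
                "  " + match[s:e],
                "B " + seq_b[s:e],
                "  " + rows_b[s:e],
                "",
            ]
        blocks.append("\n".join(lines))
    return "\n".join(blocks)


def render_comparison_html(
    seq_a: str,
    seq_b: str,
    comparison: ComparisonResult,
    id_a: str = "seq_a",
    id_b: str = "seq_b",
) -> str:
    """HTML rendering: blue = significant in both, orange = one sequence only."""

    def colored(seq: str, shared: frozenset[int], specific: frozenset[int]) -> str:
        out = []
        for i, c in enumerate(seq, start=1):
            if i in shared:
                out.append(f'<span style="color:blue">{c}</span>')
            elif i in specific:
                out.append(f'<span style="color:orange">{c}</span>')
            else:
                out.append(c)
        return "".join(out)

    match = "".join("|" if a == b else "-" for a, b in zip(seq_a, seq_b))
    rows = ["<html><body><pre>"]
    for t in comparison.temperatures:
        rows.append(f"# elevated temperature {t} C ({id_a} vs {id_b})")
        rows.append("  " + _ruler(len(seq_a)))
        rows.append("A " + colored(seq_a, comparison.shared_positions[t], comparison.specific_positions_a[t]))
        rows.append("  " + match)
        rows.append("B " + colored(seq_b, comparison.shared_positions[t], comparison.specific_positions_b[t]))
        rows.append("")
    rows.append("</pre></body></html>")
    return "\n".join(rows)
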