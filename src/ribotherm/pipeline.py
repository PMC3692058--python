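"""End-to-end orchestration and result serialization.

``run_single`` scans one sequence; ``run_pair`` scans two equal-length
sequences with identical parameters, classifies shared vs
sequence-specific significant positions and clusters, and (unless
disabled) generates the in-silico mutant data set and tests every
sequence-specific cluster with the exact binomial test.

``write_bundle`` emits the machine-readable counterparts of every result
table: a JSON summary plus TSV tables (general info, cluster locations,
histogram values, sliding-window density, length/density scatter,
cluster tests), the annotated comparison text/HTML, and the mutant FASTA.
Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    Cluster,
    ClusterSummary,
    DbscanParams,
    cluster_summary,
    dbscan_1d,
    density_profile,
)
from .fold import FoldOptions, vienna_version
from .mutagen import (
    DEFAULT_N_MUTANTS,
    MutagenError,
    MutantSet,
    spectrum_mutants,
    synonymous_mutants,
)
from .pairwise import (
    ComparisonResult,
    classify_positions,
    cluster_onset,
    onset_temperature,
    render_comparison_html,
    render_comparison_text,
    specific_clusters,
)
from .scan import (
    DEFAULT_THRESHOLD_SD,
    DiffDataset,
    PairingProfile,
    SignificantPositions,
    diff_dataset,
    scan,
    significant_positions,
)
from .sequences import (
    RnaSequence,
    SubstitutionSpectrum,
    TemperatureRange,
    substitution_spectrum,
    validate_pair,
    validate_range,
    write_fasta,
)
from .stats import ClusterTest, cluster_test


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a run (defaults mirror the server's)."""

    trange: TemperatureRange = TemperatureRange(32, 39)
    threshold_sd: float = DEFAULT_THRESHOLD_SD
    dbscan: DbscanParams = DbscanParams()
    fold: FoldOptions = FoldOptions()
    is_coding: bool = True
    skip_mutants: bool = False
    n_mutants: int = DEFAULT_N_MUTANTS
    seed: int = 0
    backend: str = "reference"
    cluster_all_temperatures: bool = False  # default: top difference only

    def to_dict(self) -> dict:
        return {
            "t1": self.trange.t1,
            "t2": self.trange.t2,
            "threshold_sd": self.threshold_sd,
            "eps": self.dbscan.eps,
            "min_pts": self.dbscan.min_pts,
            "no_gu": self.fold.no_gu,
            "no_close_gu": self.fold.no_close_gu,
            "is_coding": self.is_coding,
            "skip_mutants": self.skip_mutants,
            "n_mutants": self.n_mutants,
            "seed": self.seed,
            "backend": self.backend,
            "cluster_all_temperatures": self.cluster_all_temperatures,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            trange=TemperatureRange(d["t1"], d["t2"]),
            threshold_sd=d["threshold_sd"],
            dbscan=DbscanParams(d["eps"], d["min_pts"]),
            fold=FoldOptions(d["no_gu"], d["no_close_gu"]),
            is_coding=d["is_coding"],
            skip_mutants=d["skip_mutants"],
            n_mutants=d["n_mutants"],
            seed=d["seed"],
            backend=d["backend"],
            cluster_all_temperatures=d["cluster_all_temperatures"],
        )


@dataclass(frozen=True)
class SingleResult:
    """Everything computed for one sequence."""

    seq: RnaSequence
    config: RunConfig
    profile: PairingProfile
    diffs: DiffDataset
    significant: SignificantPositions
    clusters: tuple[Cluster, ...]
    summary: ClusterSummary
    density: np.ndarray = field(repr=False)

    @property
    def top_positions(self) -> frozenset[int]:
        return self.significant.positions_at(self.significant.top_temperature)

    def onsets(self) -> dict[int, int]:
        """Onset temperature for every position significant anywhere."""
        anywhere = np.flatnonzero(self.significant.flags.any(axis=0)) + 1
        return {int(p): onset_temperature(self.significant, int(p)) for p in anywhere}


@dataclass(frozen=True)
class PairResult:
    a: SingleResult
    b: SingleResult
    comparison: ComparisonResult
    spectrum: SubstitutionSpectrum
    mutants: MutantSet | None
    mutant_clusters: tuple[tuple[Cluster, ...], ...]
    cluster_tests: tuple[ClusterTest, ...]
    notices: tuple[str, ...]


def _cluster_positions(sig: SignificantPositions, config: RunConfig) -> set[int]:
    if config.cluster_all_temperatures:
        out: set[int] = set()
        for t in sig.temperatures:
            out |= sig.positions_at(t)
        return out
    return set(sig.positions_at(sig.top_temperature))


def run_single(seq: RnaSequence, config: RunConfig = RunConfig()) -> SingleResult:
    """Scan, outlier calling, clustering and profiles for one sequence."""
    validate_range(config.trange)
    profile = scan(seq, config.trange, config.fold, backend=config.backend)
    ds = diff_dataset(profile)
    sig = significant_positions(ds, config.threshold_sd)
    positions = _cluster_positions(sig, config)
    clusters = tuple(dbscan_1d(positions, config.dbscan))
    return SingleResult(
        seq=seq,
        config=config,
        profile=profile,
        diffs=ds,
        significant=sig,
        clusters=clusters,
        summary=cluster_summary(list(clusters)),
        density=density_profile(positions, len(seq), config.dbscan.eps),
    )


def _analyze_mutants(
    parent: RnaSequence,
    spectrum: SubstitutionSpectrum,
    config: RunConfig,
) -> tuple[MutantSet | None, tuple[tuple[Cluster, ...], ...], list[str]]:
    notices: list[str] = []
    if spectrum.count == 0:
        return None, (), ["sequences are identical; mutant analysis skipped"]
    try:
        if config.is_coding:
            mutants = synonymous_mutants(
                parent, spectrum.count, config.n_mutants, config.seed
            )
        else:
            mutants = spectrum_mutants(
                parent, spectrum, config.n_mutants, config.seed
            )
    except MutagenError as exc:
        return None, (), [f"mutant generation infeasible: {exc}; tests skipped"]
    per_mutant = []
    for mut in mutants.sequences:
        profile = scan(mut, config.trange, config.fold, backend=config.backend)
        sig = significant_positions(diff_dataset(profile), config.threshold_sd)
        per_mutant.append(tuple(dbscan_1d(_cluster_positions(sig, config), config.dbscan)))
    return mutants, tuple(per_mutant), notices


def run_pair(
    seq_a: RnaSequence, seq_b: RnaSequence, config: RunConfig = RunConfig()
) -> PairResult:
    """Full two-sequence comparison with optional specificity testing.

    Both sequences are processed with identical parameters. Mutants are
    derivatives of the first sequence; clusters specific to the first
    sequence are tested in the "disappear" direction, clusters specific
    to the second in the "appear" direction.
    """
    validate_pair(seq_a, seq_b)
    res_a = run_single(seq_a, config)
    res_b = run_single(seq_b, config)
    comparison = classify_positions(res_a.significant, res_b.significant)
    spec_a, spec_b = specific_clusters(list(res_a.clusters), list(res_b.clusters))
    comparison = ComparisonResult(
        temperatures=comparison.temperatures,
        shared_positions=comparison.shared_positions,
        specific_positions_a=comparison.specific_positions_a,
        specific_positions_b=comparison.specific_positions_b,
        specific_clusters_a=tuple(spec_a),
        specific_clusters_b=tuple(spec_b),
    )
    spectrum = substitution_spectrum(seq_a, seq_b)
    notices: list[str] = []
    mutants: MutantSet | None = None
    mutant_clusters: tuple[tuple[Cluster, ...], ...] = ()
    tests: list[ClusterTest] = []
    if config.skip_mutants:
        notices.append("mutant data set disabled by configuration")
    else:
        mutants, mutant_clusters, mnotes = _analyze_mutants(seq_a, spectrum, config)
        notices.extend(mnotes)
        if mutants is not None:
            for c in spec_a:
                tests.append(cluster_test(c, "disappear", list(mutant_clusters)))
            for c in spec_b:
                tests.append(cluster_test(c, "appear", list(mutant_clusters)))
            if len(tests) > 1:
                notices.append(
                    f"{len(tests)} clusters tested without multiple-testing "
                    "correction; apply your own if needed"
                )
    return PairResult(
        a=res_a,
        b=res_b,
        comparison=comparison,
        spectrum=spectrum,
        mutants=mutants,
        mutant_clusters=mutant_clusters,
        cluster_tests=tuple(tests),
        notices=tuple(notices),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _seq_label(res: SingleResult, fallback: str) -> str:
    return res.seq.id or fallback


def _general_info_row(res: SingleResult, label: str) -> dict:
    sig = res.significant
    return {
        "sequence": label,
        "n_significant": len(res.top_positions),
        "total_length": len(res.seq),
        "signif_pos_neg": len(sig.decrease_set),
        "signif_pos_pos": len(sig.increase_set),
        "n_clusters": res.summary.n_clusters,
        "avg_cluster_density": res.summary.avg_density,
        "avg_cluster_length": res.summary.avg_length,
    }


def _cluster_table(res: SingleResult) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": i + 1,
            "start": c.start,
            "end": c.end,
            "length": c.length,
            "n_members": len(c.members),
            "density": c.density,
            "onset_temperature": cluster_onset(res.significant, c),
        }
        for i, c in enumerate(res.clusters)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "start", "end", "length", "n_members", "density",
            "onset_temperature",
        ],
    )


def _summary_dict(result: SingleResult | PairResult) -> dict:
    if isinstance(result, SingleResult):
        singles = [(result, "seq1")]
        pair = None
    else:
        singles = [(result.a, "seq1"), (result.b, "seq2")]
        pair = result
    out = {
        "package_version": __version__,
        "backend": singles[0][0].config.backend,
        "backend_version": vienna_version()
        if singles[0][0].config.backend == "vienna"
        else __version__,
        "config": singles[0][0].config.to_dict(),
        "sequences": {},
    }
    for res, fallback in singles:
        label = _seq_label(res, fallback)
        entry = _general_info_row(res, label)
        entry["combined_dataset_size"] = int(res.diffs.combined.size)
        entry["mean"] = res.diffs.mean
        entry["sd"] = res.diffs.sd
        entry["clusters"] = [
            {"start": c.start, "end": c.end, "n_members": len(c.members)}
            for c in res.clusters
        ]
        entry["onset_temperatures"] = {
            str(p): t for p, t in sorted(res.onsets().items())
        }
        if res.summary.n_clusters == 0:
            entry["note"] = "no clusters were identified"
        out["sequences"][label] = entry
    if pair is not None:
        out["comparison"] = {
            "n_substitutions": pair.spectrum.count,
            "substitution_positions": list(pair.spectrum.positions),
            "substitution_spectrum": {
                f"{a}->{b}": f for (a, b), f in sorted(pair.spectrum.type_frequencies.items())
            },
            "specific_clusters_seq1": [
                {"start": c.start, "end": c.end} for c in pair.comparison.specific_clusters_a
            ],
            "specific_clusters_seq2": [
                {"start": c.start, "end": c.end} for c in pair.comparison.specific_clusters_b
            ],
            "notices": list(pair.notices),
        }
        out["cluster_tests"] = [
            {
                "start": t.cluster.start,
                "end": t.cluster.end,
                "direction": t.direction,
                "k": t.k,
                "n": t.n,
                "frequency": t.frequency,
                "p_value": t.p_value,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "null_boundary": t.null_boundary,
            }
            for t in pair.cluster_tests
        ]
    return out


def write_bundle(result: SingleResult | PairResult, outdir) -> Path:
    """Write all tables and data files for a run into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, SingleResult):
        singles = [(result, "seq1")]
        pair = None
    else:
        singles = [(result.a, "seq1"), (result.b, "seq2")]
        pair = result

    info = pd.DataFrame([_general_info_row(r, _seq_label(r, fb)) for r, fb in singles])
    info.to_csv(outdir / "general_info.tsv", sep="\t", index=False)

    for res, fallback in singles:
        label = _seq_label(res, fallback)
        safe = "".join(ch if ch.isalnum() else "_" for ch in label)[:40]
        _cluster_table(res).to_csv(outdir / f"clusters_{safe}.tsv", sep="\t", index=False)
        pd.DataFrame({"difference": res.diffs.combined}).to_csv(
            outdir / f"histogram_{safe}.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "window_start": np.arange(1, res.density.size + 1),
                "percent": res.density,
            }
        ).to_csv(outdir / f"density_{safe}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "length": [c.length for c in res.clusters],
                "density": [c.density for c in res.clusters],
            }
        ).to_csv(outdir / f"scatter_{safe}.tsv", sep="\t", index=False)

    if pair is not None:
        text = render_comparison_text(
            pair.a.seq.residues,
            pair.b.seq.residues,
            pair.comparison,
            id_a=_seq_label(pair.a, "seq1"),
            id_b=_seq_label(pair.b, "seq2"),
        )
        (outdir / "comparison.txt").write_text(text)
        html = render_comparison_html(
            pair.a.seq.residues,
            pair.b.seq.residues,
            pair.comparison,
            id_a=_seq_label(pair.a, "seq1"),
            id_b=_seq_label(pair.b, "seq2"),
        )
        (outdir / "comparison_html.txt").write_text(html)
        pd.DataFrame(
            [
                {
                    "start": t.cluster.start,
                    "end": t.cluster.end,
                    "direction": t.direction,
                    "k": t.k,
                    "n": t.n,
                    "frequency": t.frequency,
                    "p_value": t.p_value,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                }
                for t in pair.cluster_tests
            ],
            columns=[
                "start", "end", "direction", "k", "n", "frequency", "p_value",
                "ci_low", "ci_high",
            ],
        ).to_csv(outdir / "cluster_tests.tsv", sep="\t", index=False)
        if pair.mutants is not None:
            write_fasta(list(pair.mutants.sequences), outdir / "mutants.fasta")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_summary_dict(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
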