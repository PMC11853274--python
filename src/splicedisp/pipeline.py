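"""End-to-end runs: catalog -> filter -> extract -> count -> dispersion -> tests.

Two entry points: :func:`run_annotation_mode` takes a genome FASTA and a
GTF; :func:`run_synthetic_mode` drives the synthetic generator.  Both emit
the same output bundle (mode table, windows, per-mode dispersion profiles,
region test tables) plus a JSON run manifest whose record counts reconcile
with the rejection logs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from . import catalog as cat
from . import dispersion as disp
from . import region_stats as rs
from . import simulate as sim
from . import windows as win
from .kmers import SubsetPartition


@dataclass
class PipelineConfig:
    """Thresholds and bounds governing a run."""

    min_intron_span: int = win.MIN_INTRON_SPAN
    min_alt_separation: int = win.MIN_ALT_SEPARATION
    reject_n: bool = True
    canonical_only: bool = True
    alpha: float = 0.05
    regions: Tuple[Tuple[str, int, int], ...] = tuple(
        (r.name, r.start_label, r.end_label) for r in rs.DEFAULT_REGIONS
    )

    def region_specs(self) -> Tuple[rs.RegionSpec, ...]:
        return tuple(rs.RegionSpec(*r) for r in self.regions)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "regions" in raw:
            raw["regions"] = tuple(tuple(r) for r in raw["regions"])
        return cls(**raw)


@dataclass
class RunManifest:
    """Bookkeeping for one run: inputs, config, per-stage counts, outputs."""

    inputs: Dict[str, str]
    config: Dict
    seed: Optional[int]
    counts: Dict[str, int] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _config_digest(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _profiles_by_group(
    windows: List[win.AcceptorWindow],
    group_key: str,
    partition: SubsetPartition,
    min_windows: int = 1,
) -> Tuple[Dict[str, pd.DataFrame], List[str]]:
    """Tidy dispersion profile per window group; drops empty/small groups."""
    groups: Dict[str, List[win.AcceptorWindow]] = {}
    for w in windows:
        groups.setdefault(getattr(w, group_key), []).append(w)
    profiles, dropped = {}, []
    for name in sorted(groups):
        if len(groups[name]) < min_windows:
            dropped.append(name)
            continue
        matrix = disp.count_kmers_by_site(groups[name])
        profiles[name] = disp.profile(matrix, partition)
    return profiles, dropped


def _write_profiles(profiles: Mapping[str, pd.DataFrame], path, group_key: str) -> None:
    frames = []
    for name, df in profiles.items():
        frames.append(df.assign(**{group_key: name}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def _finalize(
    out: Path,
    manifest: RunManifest,
    windows: List[win.AcceptorWindow],
    config: PipelineConfig,
    partition: SubsetPartition,
    bundle: Dict,
) -> Dict:
    """Profile + test stages shared by both run modes."""
    win.windows_to_fasta(windows, out / "windows.fasta")
    win.windows_to_frame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    manifest.outputs["windows_fasta"] = str(out / "windows.fasta")
    manifest.outputs["windows_tsv"] = str(out / "windows.tsv")

    comparisons = {"mode": windows}
    alt = [
        w for w in windows
        if w.mode == "alternative" and w.submode in ("normal", "exonic", "intronic")
    ]
    if alt:
        comparisons["submode"] = alt
    for group_key, group_windows in comparisons.items():
        profiles, dropped = _profiles_by_group(group_windows, group_key, partition)
        if dropped:
            manifest.counts[f"dropped_{group_key}_groups"] = len(dropped)
        if not profiles:
            continue
        ppath = out / f"profiles_{group_key}.tsv"
        _write_profiles(profiles, ppath, group_key)
        manifest.outputs[f"profiles_{group_key}"] = str(ppath)
        bundle[f"profiles_{group_key}"] = profiles
        if len(profiles) >= 2:
            tests = rs.compare_modes(
                profiles, regions=config.region_specs(), alpha=config.alpha
            )
            tpath = out / f"region_tests_{group_key}.tsv"
            tests.to_csv(tpath, sep="\t", index=False)
            manifest.outputs[f"region_tests_{group_key}"] = str(tpath)
            bundle[f"region_tests_{group_key}"] = tests
    manifest.counts["n_windows"] = len(windows)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def run_annotation_mode(
    genome_path,
    gtf_path,
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> Dict:
    """Full annotation-driven run; returns the result bundle."""
    from pyfaidx import Fasta

    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        inputs={"genome": str(genome_path), "gtf": str(gtf_path)},
        config={**asdict(config), "digest": _config_digest(config)},
        seed=None,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    models = cat.read_transcript_exons(gtf_path)
    events = cat.infer_events(models)
    catalog_df = cat.classify_acceptors(events, models)
    events_df = cat.events_frame(events, catalog_df)
    catalog_df.to_csv(out / "acceptors.tsv", sep="\t", index=False)
    cat.catalog_to_bed(catalog_df).to_csv(
        out / "acceptors.bed", sep="\t", index=False, header=False
    )
    manifest.outputs["acceptors_tsv"] = str(out / "acceptors.tsv")
    manifest.outputs["acceptors_bed"] = str(out / "acceptors.bed")
    manifest.counts["n_transcripts"] = len(models)
    manifest.counts["n_events"] = len(events_df)
    manifest.counts["n_acceptors"] = len(catalog_df)

    retained, rejections = win.filter_events(
        events_df,
        min_intron_span=config.min_intron_span,
        min_alt_separation=config.min_alt_separation,
    )
    manifest.counts["n_events_retained"] = len(retained)
    manifest.counts["n_events_rejected"] = int(
        rejections.drop_duplicates(["chrom", "strand", "donor_pos", "acceptor_pos"]).shape[0]
    )

    genome = Fasta(str(genome_path), sequence_always_upper=True)
    missing = sorted(
        {c for c in retained["chrom"].unique() if c not in set(genome.keys())}
    )
    if missing:
        raise KeyError(f"contigs in annotation missing from genome: {missing}")
    windows, window_log = win.extract_windows(
        genome, retained, reject_n=config.reject_n, canonical_only=config.canonical_only
    )
    log = pd.concat([rejections, window_log], ignore_index=True)
    log.to_csv(out / "rejections.tsv", sep="\t", index=False)
    manifest.outputs["rejections"] = str(out / "rejections.tsv")

    bundle = {"catalog": catalog_df, "events": events_df, "rejections": log,
              "windows": windows}
    return _finalize(out, manifest, windows, config, SubsetPartition.build(6), bundle)


def run_synthetic_mode(
    generator: sim.GeneratorConfig,
    out_dir,
    modes: Iterable[str] = ("common", "constitutive", "alternative"),
    config: Optional[PipelineConfig] = None,
) -> Dict:
    """Synthetic end-to-end run over the given mode labels."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        inputs={"generator": "synthetic"},
        config={
            **asdict(config),
            "generator": {
                **asdict(generator),
                "core_weights": {str(k): v for k, v in generator.core_weights.items()},
            },
            "digest": _config_digest(config),
        },
        seed=generator.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    windows: List[win.AcceptorWindow] = []
    for mode in modes:
        windows.extend(sim.generate_windows(generator, mode=mode))
    manifest.counts["n_modes"] = len(list(modes))
    bundle: Dict = {"generator": generator}
    return _finalize(out, manifest, windows, config, SubsetPartition.build(6), bundle)
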