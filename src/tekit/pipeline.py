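"""Run configuration, stage orchestration, and reproducible manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment_io import (
    FormatError,
    build_families,
    read_canonical_alignments,
    read_family_map,
    read_fasta,
    read_repeatmasker_align,
    write_canonical_alignments,
    write_fasta,
)
from . import dna_loss, landscape, synthetic_data, te_age

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable threshold, with defaults from the study being emulated."""

    # te_age copy filter
    min_copy_len: int = 100
    min_identity: float = 0.80
    min_shared_subs: int = 2
    min_copies_shared: int = 2
    bin_width_pct: float = 1.0
    weighting: str = "bp"
    total_data_bp: int = 0  # 0 -> use the summed weight of retained copies
    # dna_loss
    consensus_min_len: int = 330
    consensus_min_copies: int = 5
    consensus_copy_min_len: int = 300
    consensus_copy_min_identity: float = 0.80
    alpha: float = 0.05
    indel_cap: int = 30
    homopolymer_min_run: int = 5
    # landscape
    genome_size_gb: float = 55.0
    dataset_bp: int = 0
    # inputs / outputs
    alignments: str = ""
    alignment_format: str = "auto"  # auto | canonical | repeatmasker
    consensus_fasta: str = ""
    family_map: str = ""
    annotations: str = ""
    preset: str = "old_burst"
    seed: int = 0
    out_dir: str = "tekit_out"

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# tekit run configuration (key: value)\n")
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}: {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise FormatError(f"{path}: line {lineno}: expected 'key: value'")
                key, _, value = line.partition(":")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    values[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    values[key] = int(value)
                elif isinstance(current, float):
                    values[key] = float(value)
                else:
                    values[key] = value
        return cls(**values)

    def overrides(self) -> dict[str, object]:
        """Fields differing from the defaults (recorded in the manifest)."""
        defaults = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(defaults, f.name)
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_alignments(config: RunConfig):
    path = Path(config.alignments)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    fmt = config.alignment_format
    if fmt == "auto":
        fmt = "repeatmasker" if path.suffix == ".align" else "canonical"
    if fmt == "repeatmasker":
        return read_repeatmasker_align(path)
    return read_canonical_alignments(path)


def _build_input_families(config: RunConfig):
    alignments = _load_alignments(config)
    consensus = None
    if config.consensus_fasta:
        consensus = dict(read_fasta(config.consensus_fasta))
    superfamilies = None
    if config.family_map:
        superfamilies = read_family_map(config.family_map)
    return build_families(alignments, consensus, superfamilies)


def simulate_stage(config: RunConfig, out: Path) -> tuple[list, dict[str, object]]:
    presets = synthetic_data.preset_scenarios(seed=config.seed)
    if config.preset not in presets:
        raise ValueError(
            f"unknown preset {config.preset!r}; choose from {sorted(presets)}"
        )
    scenario = presets[config.preset]
    family, truth = synthetic_data.simulate_family(scenario)
    reads, _ = synthetic_data.shred_to_reads(family, scenario)

    write_fasta([(family.family_id, family.consensus)], out / "master.fasta")
    write_fasta(
        [(a.copy_id, a.ungapped_copy()) for a in family.alignments],
        out / "copies.fasta",
    )
    write_fasta(reads, out / "reads.fasta")
    write_canonical_alignments(family.alignments, out / "alignments.aln")
    pd.DataFrame(synthetic_data.truth_to_rows(truth)).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    with open(out / "family_map.tsv", "w") as fh:
        fh.write(f"{family.family_id}\t{family.superfamily}\n")
    info = {
        "preset": config.preset,
        "n_copies": family.n_copies,
        "n_reads": len(reads),
        "outputs": ["master.fasta", "copies.fasta", "reads.fasta",
                    "alignments.aln", "truth.tsv", "family_map.tsv"],
    }
    return [family], info


def te_age_stage(config: RunConfig, families, out: Path) -> dict[str, object]:
    all_records = []
    n_raw = 0
    for family in families:
        flagged = te_age.detect_master_substitutions(
            family,
            min_shared_subs=config.min_shared_subs,
            min_copies=config.min_copies_shared,
        )
        records = te_age.divergence_records(family, flagged)
        n_raw += len(records)
        all_records.extend(
            te_age.filter_copies(
                records,
                min_len_bp=config.min_copy_len,
                min_identity=config.min_identity,
            )
        )
    logger.info("te_age: %d/%d copies pass the length/identity filter",
                len(all_records), n_raw)
    pd.DataFrame([dataclasses.asdict(r) for r in all_records]).to_csv(
        out / "divergence.tsv", sep="\t", index=False
    )
    info: dict[str, object] = {
        "copies_read": n_raw,
        "copies_retained": len(all_records),
        "outputs": ["divergence.tsv"],
    }
    if all_records:
        hist = te_age.age_histogram(
            all_records,
            bin_width_pct=config.bin_width_pct,
            weighting=config.weighting,
            total_data=config.total_data_bp or None,
        )
        pd.DataFrame(hist.to_rows(), columns=["bin_low", "bin_high", "percent"]).to_csv(
            out / "age_histogram.tsv", sep="\t", index=False
        )
        info["outputs"].append("age_histogram.tsv")
        info["mode_bin_low"] = hist.bin_edges[hist.mode_bin]
    return info


def dna_loss_stage(config: RunConfig, families, out: Path) -> dict[str, object]:
    non_ltr = [f for f in families if f.te_class == "non-LTR"]
    if non_ltr:
        targets = non_ltr
    else:
        logger.warning("dna_loss: no non-LTR families; tallying all %d families",
                       len(families))
        targets = families
    retained, acceptances, codon_tests = dna_loss.screen_families(
        targets,
        alpha=config.alpha,
        min_consensus_len=config.consensus_min_len,
        min_copies=config.consensus_min_copies,
        min_copy_len=config.consensus_copy_min_len,
        min_identity=config.consensus_copy_min_identity,
    )
    result = dna_loss.loss_rate(
        retained,
        min_run=config.homopolymer_min_run,
        indel_cap=config.indel_cap,
        screen=False,
    )
    pd.DataFrame([dataclasses.asdict(result)]).to_csv(
        out / "loss_rate.tsv", sep="\t", index=False
    )
    rows = []
    for t in codon_tests:
        rows.append(
            {
                "family_id": t.family_id, "n1": t.counts[0], "n2": t.counts[1],
                "n3": t.counts[2], "chi2_stat": t.chi2_stat, "p_value": t.p_value,
                "excluded": t.excluded, "tested": t.tested,
            }
        )
    pd.DataFrame(
        rows, columns=["family_id", "n1", "n2", "n3", "chi2_stat", "p_value",
                       "excluded", "tested"]
    ).to_csv(out / "codon_tests.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(a) for a in acceptances]).to_csv(
        out / "consensus_acceptance.tsv", sep="\t", index=False
    )
    return {
        "families_considered": len(targets),
        "families_retained": len(retained),
        "families_chi2_excluded": sum(1 for t in codon_tests if t.excluded),
        "loss_rate": result.loss_rate,
        "outputs": ["loss_rate.tsv", "codon_tests.tsv", "consensus_acceptance.tsv"],
    }


def landscape_stage(config: RunConfig, out: Path) -> dict[str, object]:
    records = landscape.read_annotations(config.annotations)
    resolved = landscape.resolve_overlaps(records)
    summary = landscape.summarize(
        resolved, genome_size_gb=config.genome_size_gb, dataset_bp=config.dataset_bp
    )
    summary.to_dataframe().to_csv(out / "landscape.tsv", sep="\t", index=False)
    return {
        "annotations": len(records),
        "coverage_pct": summary.coverage_pct,
        "outputs": ["landscape.tsv"],
    }


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run all applicable stages; returns (and writes) the run manifest.

    With no input alignments a preset family is simulated first.  The
    manifest records the package version, full config, threshold overrides,
    and SHA-256 digests of every input, so a run can be reproduced exactly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "tool": "tekit",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_overrides": config.overrides(),
        "inputs": {},
        "stages": {},
    }
    for name in ("alignments", "consensus_fasta", "family_map", "annotations"):
        path = getattr(config, name)
        if path:
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    try:
        if config.alignments:
            families = _build_input_families(config)
        else:
            families, sim_info = simulate_stage(config, out)
            manifest["stages"]["simulate"] = sim_info
        manifest["stages"]["te_age"] = te_age_stage(config, families, out)
        manifest["stages"]["dna_loss"] = dna_loss_stage(config, families, out)
        if config.annotations:
            if config.dataset_bp <= 0:
                raise ValueError("landscape stage requires dataset_bp > 0")
            manifest["stages"]["landscape"] = landscape_stage(config, out)
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "input"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
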