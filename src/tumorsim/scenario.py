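"""Multi-sample scenario runs: dilution series and longitudinal designs.

A scenario couples one genome profile (shared germline SNPs and declared
somatic events) with a list of sample plans, each optionally overriding
the global tumor content and per-clone clonality. Typical uses are a
serial dilution of tumor content with fixed events, and a longitudinal
series where one subclone regresses (clonality driven toward zero) while
another emerges. Every scenario run also emits one matched control and a
combined per-event report of expected versus observed allelic fractions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import yaml

from tumorsim import __version__
from tumorsim.errors import ValidationError
from tumorsim.engine import generate_sample
from tumorsim.models import load_models
from tumorsim.profiles import (
    GenomeProfile,
    SamplePlan,
    SomaticCNA,
    SomaticPM,
    parse_cnas,
    parse_pms,
    parse_snps,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ScenarioConfig:
    """Parsed scenario description (see ``load_scenario``)."""

    models: str
    reference: str
    snps: str
    cnas: str | None
    pms: str | None
    samples: list[dict]
    read_length: int = 100
    paired: bool = True
    strand_bias: float = 0.5
    seed: int = 0
    coverage: float | None = None
    n_reads: int | None = None
    control_coverage: float | None = None


def load_scenario(path: str) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return ScenarioConfig(**raw)
    except TypeError as exc:
        raise ValidationError(f"bad scenario config {path}: {exc}") from exc


def _override_clonality(
    profile: GenomeProfile, overrides: dict[str, float]
) -> GenomeProfile:
    """Per-sample clonality overrides; 0 removes the clone's events."""
    declared = {c.clone_id for c in profile.cnas} | {p.clone_id for p in profile.pms}
    unknown = set(overrides) - declared
    if unknown:
        raise ValidationError(f"clonality overrides for undeclared clones: {sorted(unknown)}")
    cnas: list[SomaticCNA] = []
    for cna in profile.cnas:
        c = overrides.get(cna.clone_id, cna.clonality)
        if c > 0:
            cnas.append(dataclasses.replace(cna, clonality=c))
    pms: list[SomaticPM] = []
    for pm in profile.pms:
        c = overrides.get(pm.clone_id, pm.clonality)
        if c > 0:
            pms.append(dataclasses.replace(pm, clonality=c))
    return GenomeProfile(snps=profile.snps, cnas=cnas, pms=pms)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_scenario(config: ScenarioConfig, out_dir: str, workers: int = 1) -> dict:
    """Generate every planned tumor sample plus one matched control.

    All validation happens before any generation starts, so a broken
    sample definition aborts the whole run up front. Returns the combined
    report (also written to ``<out_dir>/scenario_report.json``).
    """
    os.makedirs(out_dir, exist_ok=True)
    models = load_models(config.models)
    profile = GenomeProfile(
        snps=parse_snps(config.snps),
        cnas=parse_cnas(config.cnas) if config.cnas else [],
        pms=parse_pms(config.pms) if config.pms else [],
    )
    errors: list[str] = []
    prepared: list[tuple[SamplePlan, GenomeProfile]] = []
    for i, sample in enumerate(config.samples):
        try:
            name = sample.get("name", f"sample{i + 1}")
            tc = float(sample["tumor_content"])
            overrides = {
                str(k): float(v)
                for k, v in sample.get("clonality_overrides", {}).items()
            }
            sample_profile = _override_clonality(profile, overrides)
            plan = SamplePlan(
                sample_name=name,
                sample_kind="tumor",
                tumor_content=tc,
                target_mean_coverage=sample.get("coverage", config.coverage),
                n_reads=sample.get("n_reads", config.n_reads),
                read_length=config.read_length,
                paired=config.paired,
                strand_bias=config.strand_bias,
                seed=int(sample.get("seed", config.seed + i + 1)),
            )
            prepared.append((plan, sample_profile))
        except (KeyError, ValueError, ValidationError) as exc:
            errors.append(f"sample {i + 1}: {exc}")
    if errors:
        raise ValidationError("; ".join(errors))

    control_plan = SamplePlan(
        sample_name="control",
        sample_kind="matched_control",
        tumor_content=0.0,
        target_mean_coverage=config.control_coverage or config.coverage,
        n_reads=None if (config.control_coverage or config.coverage) else config.n_reads,
        read_length=config.read_length,
        paired=config.paired,
        strand_bias=config.strand_bias,
        seed=config.seed,
    )
    reports = []
    report = generate_sample(
        models,
        profile,
        control_plan,
        config.reference,
        os.path.join(out_dir, "control"),
        workers=workers,
    )
    reports.append(report)
    for plan, sample_profile in prepared:
        log.info("generating sample %s (t=%.2f)", plan.sample_name, plan.tumor_content)
        reports.append(
            generate_sample(
                models,
                sample_profile,
                plan,
                config.reference,
                os.path.join(out_dir, plan.sample_name),
                workers=workers,
            )
        )
    combined = {
        "provenance": {
            "tumorsim_version": __version__,
            "seed": config.seed,
            "inputs": {
                key: _sha256(path)
                for key, path in {
                    "models": config.models,
                    "reference": config.reference,
                    "snps": config.snps,
                    "cnas": config.cnas,
                    "pms": config.pms,
                }.items()
                if path
            },
        },
        "samples": reports,
    }
    with open(os.path.join(out_dir, "scenario_report.json"), "w") as fh:
        json.dump(combined, fh, indent=1)
    _write_events_tsv(reports, os.path.join(out_dir, "scenario_events.tsv"))
    return combined


def _write_events_tsv(reports: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample\tkind\tevent\tchromosome\tposition\t"
            "expected\tobserved\tdepth\n"
        )
        for rep in reports:
            for row in rep["snps"]:
                fh.write(
                    f"{rep['sample']}\t{rep['sample_kind']}\tsnp_baf\t"
                    f"{row['chromosome']}\t{row['position']}\t"
                    f"{row['expected_baf_alt']}\t{row['observed_baf_alt']}\t"
                    f"{row['depth']}\n"
                )
            for row in rep["pms"]:
                fh.write(
                    f"{rep['sample']}\t{rep['sample_kind']}\tpm_vaf\t"
                    f"{row['chromosome']}\t{row['position']}\t"
                    f"{row['expected_vaf']}\t{row['observed_vaf']}\t"
                    f"{row['depth']}\n"
                )
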