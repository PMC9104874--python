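"""End-to-end pipeline: filter -> enrich -> permute -> loh -> clinical.

A single YAML config drives one reproducible run. Every input may be a
file path; inputs left unset fall back to the packaged reference study
profiles (the candidate variant panel, the replication cohort built
from its published counts, the encoded LOH states) or, for the
clinical stage, to synthetic demonstration arms. All randomness is
funnelled through one global seed, and a manifest recording the config
hash and seed makes reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io, study
from .clinical import compare_carrier_groups
from .filtering import FilterConfig, run_filter_cascade, apply_quality_filters
from .loh import LOHThresholds, call_loh
from .permutation import PermutationConfig, run_permutation_study
from .stats import pairwise_case_control_tests
from .synthetic import generate_clinical_table, generate_cohort
from .types import Cohort

log = logging.getLogger("carrierscan")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    out_dir: Path
    variants_path: Path | None = None
    calls_path: Path | None = None
    cohort_path: Path | None = None
    loh_path: Path | None = None
    clinical_path_a: Path | None = None
    clinical_path_b: Path | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    n_permutations: int = 5000
    alpha: float = 0.05
    allocation_unit: str = "carrier"
    loh_thresholds: LOHThresholds = field(default_factory=LOHThresholds)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        def resolve(key: str) -> Path | None:
            value = raw.get(key)
            if value is None:
                return None
            p = Path(value)
            p = p if p.is_absolute() else base / p
            if not p.exists():
                raise FileNotFoundError(f"config path {key}={value!r} does not exist")
            return p

        filter_kwargs = raw.get("filter", {}) or {}
        perm = raw.get("permutation", {}) or {}
        loh_kwargs = raw.get("loh_thresholds", {}) or {}
        out_dir = Path(raw.get("out_dir", "carrierscan_out"))
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=out_dir if out_dir.is_absolute() else base / out_dir,
            variants_path=resolve("variants"),
            calls_path=resolve("calls"),
            cohort_path=resolve("cohort"),
            loh_path=resolve("loh"),
            clinical_path_a=resolve("clinical_a"),
            clinical_path_b=resolve("clinical_b"),
            filter_config=FilterConfig(**filter_kwargs),
            n_permutations=int(perm.get("n_permutations", 5000)),
            alpha=float(perm.get("alpha", 0.05)),
            allocation_unit=str(perm.get("allocation_unit", "carrier")),
            loh_thresholds=LOHThresholds(**loh_kwargs),
            raw=raw,
        )

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are; exclude it
        # so reruns into different directories compare equal
        canon = json.dumps(
            {k: v for k, v in self.raw.items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()


def _load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_path is not None:
        return io.read_cohort(config.cohort_path)
    return generate_cohort(study.study_cohort_spec(seed=config.seed))


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle under ``out_dir``.

    Returns the in-memory results keyed by stage. Reruns with an
    identical config (and seed) produce byte-identical outputs.
    """
    logging.basicConfig(stream=sys.stderr, format="%(name)s %(levelname)s %(message)s")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}

    # --- stage: filter ---------------------------------------------------
    log.info("stage=filter start")
    try:
        variants = (
            io.read_variant_table(config.variants_path)
            if config.variants_path is not None
            else study.candidate_variant_panel()
        )
        if config.calls_path is not None:
            calls = io.read_genotype_calls(config.calls_path)
            kept_calls, _ = apply_quality_filters(calls, config.filter_config)
            passing = {c.variant_id for c in kept_calls}
            variants = [v for v in variants if v.variant_id in passing]
        candidates, trace = run_filter_cascade(variants, config.filter_config)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("filter", str(exc)) from exc
    io.write_variant_table(candidates, out / "candidates.tsv")
    io.write_report(
        pd.DataFrame(
            [
                {
                    "variant_id": t.variant_id,
                    "status": t.status.value,
                    "first_failure": t.first_failure or "NA",
                    "verdicts": ";".join(f"{k}={v}" for k, v in sorted(t.verdicts.items())),
                }
                for t in trace
            ]
        ),
        out / "filter_trace.tsv",
    )
    results["candidates"] = candidates

    # --- stage: enrich ---------------------------------------------------
    log.info("stage=enrich start")
    try:
        cohort = _load_cohort(config)
        tests = pairwise_case_control_tests(cohort, pairs=study.replication_pairs())
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", str(exc)) from exc
    enrich_frame = pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "case_group": r.case_group,
                "control_group": r.control_group,
                "case_carriers": r.table[0][0],
                "case_denominator": sum(r.table[0]),
                "case_percent": r.carrier_freq_case.percent,
                "control_carriers": r.table[1][0],
                "control_denominator": sum(r.table[1]),
                "control_percent": r.carrier_freq_control.percent,
                "p_two_sided": f"{r.p_two_sided:.6g}",
            }
            for r in tests
        ]
    )
    io.write_report(enrich_frame, out / "enrichment.tsv")
    results["enrichment"] = tests
    results["cohort"] = cohort

    # --- stage: permute --------------------------------------------------
    log.info("stage=permute start")
    try:
        perm_cfg = PermutationConfig(
            seed=config.seed,
            tests=study.permutation_tests(),
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            allocation_unit=config.allocation_unit,
        )
        perm = run_permutation_study(cohort, None, perm_cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("permute", str(exc)) from exc
    io.write_report(perm, out / "permutation.json")
    results["permutation"] = perm

    # --- stage: loh ------------------------------------------------------
    log.info("stage=loh start")
    try:
        observations = (
            io.read_loh_observations(config.loh_path)
            if config.loh_path is not None
            else study.loh_observations()
        )
        calls = [call_loh(o, config.loh_thresholds) for o in observations]
    except Exception as exc:  # noqa: BLE001
        raise StageError("loh", str(exc)) from exc
    io.write_report(
        pd.DataFrame(
            [
                {
                    "carrier_id": o.carrier_id,
                    "variant_id": o.variant_id,
                    "tissue": o.tissue,
                    "preservation": o.preservation.value,
                    "state": c.state.value,
                    "wild_type_fraction": f"{c.wild_type_fraction:.4f}",
                }
                for o, c in zip(observations, calls)
            ]
        ),
        out / "loh_calls.tsv",
    )
    results["loh_calls"] = calls

    # --- stage: clinical -------------------------------------------------
    log.info("stage=clinical start")
    try:
        if config.clinical_path_a is not None and config.clinical_path_b is not None:
            arm_a = io.read_clinical_table(config.clinical_path_a)
            arm_b = io.read_clinical_table(config.clinical_path_b)
        else:
            # synthetic demonstration arms at the reported scale:
            # 15 carriers per arm, ages ~N(59, 8.4) vs ~N(54, 11)
            arm_a = generate_clinical_table(
                15, 59.0, 8.4, seed=config.seed, variant_id=study.RAD51D_620
            )
            arm_b = generate_clinical_table(
                15, 54.0, 11.0, seed=config.seed + 1, variant_id="BRCA1:c.4327C>T"
            )
        clinical = compare_carrier_groups(arm_a, arm_b, "age_at_diagnosis")
    except Exception as exc:  # noqa: BLE001
        raise StageError("clinical", str(exc)) from exc
    io.write_report(clinical, out / "clinical.json")
    results["clinical"] = clinical

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ["filter", "enrich", "permute", "loh", "clinical"],
        "n_candidates": len(candidates),
        "n_permutations": perm.n_permutations,
    }
    io.write_report(manifest, out / "manifest.json")
    results["manifest"] = manifest
    log.info("run complete")
    return results
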