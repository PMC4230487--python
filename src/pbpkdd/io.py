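"""Run configuration, CSV emission and the reproducibility manifest.

A run is fully described by a YAML config (population spec, drug fixtures,
constants file, artemether dose levels, seed).  Outputs are deterministic
for a given (config, seed, constants) triple: a subjects table, a
per-subject PK table, a summary table in median/range + mean/SD layout, and
a manifest recording the seed and the SHA-256 of every emitted file and of
the constants actually used.
"""
from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .drugs import DrugParameters, SystemConstants, builtin_drug, load_drug, load_system_constants
from .population import IndividualPhysiology, PopulationSpec
from .trial import TrialResult

__all__ = ["RunConfig", "load_run_config", "write_outputs", "population_frame"]

_TOP_KEYS = {
    "seed", "population", "drugs", "constants", "art_doses_mg",
    "output_dir", "export_profiles", "solver",
}
_POP_KEYS = {"n_subjects", "age_min", "age_max", "proportion_female"}


@dataclass
class RunConfig:
    seed: int
    population: PopulationSpec
    artemether: DrugParameters
    efavirenz: DrugParameters
    constants: SystemConstants
    art_doses_mg: tuple[float, ...] = (80.0,)
    output_dir: str = "results"
    export_profiles: bool = False
    solver: dict = field(default_factory=dict)


def _unknown_key_error(key: str, valid: set[str]) -> ValueError:
    close = difflib.get_close_matches(key, sorted(valid), n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return ValueError(f"unknown config key {key!r}{hint}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and fully validate a run configuration file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    for key in doc:
        if key not in _TOP_KEYS:
            raise _unknown_key_error(key, _TOP_KEYS)
    if "seed" not in doc:
        raise ValueError(f"{path}: mandatory field 'seed' is missing")

    pop = doc.get("population") or {}
    for key in pop:
        if key not in _POP_KEYS:
            raise _unknown_key_error(key, _POP_KEYS)
    spec = PopulationSpec(
        n_subjects=int(pop.get("n_subjects", 50)),
        age_range=(float(pop.get("age_min", 20.0)), float(pop.get("age_max", 50.0))),
        proportion_female=float(pop.get("proportion_female", 0.5)),
        random_seed=int(doc["seed"]),
    )

    def _drug(name: str) -> DrugParameters:
        ref = (doc.get("drugs") or {}).get(name, "builtin")
        if ref == "builtin":
            return builtin_drug(name)
        return load_drug(path.parent / ref)

    constants_ref = doc.get("constants", "builtin")
    constants = (
        load_system_constants()
        if constants_ref in ("builtin", None)
        else load_system_constants(path.parent / constants_ref)
    )
    return RunConfig(
        seed=int(doc["seed"]),
        population=spec,
        artemether=_drug("artemether"),
        efavirenz=_drug("efavirenz"),
        constants=constants,
        art_doses_mg=tuple(float(d) for d in doc.get("art_doses_mg", [80.0])),
        output_dir=str(doc.get("output_dir", "results")),
        export_profiles=bool(doc.get("export_profiles", False)),
        solver=dict(doc.get("solver") or {}),
    )


def population_frame(subjects: list[IndividualPhysiology]) -> pd.DataFrame:
    """One row per subject: covariates, organ masses (kg), flows (L/h)."""
    rows = []
    for i, s in enumerate(subjects):
        row = {
            "subject": i, "sex": s.sex, "age": s.age, "height_cm": s.height_cm,
            "body_weight": s.body_weight, "bmi": s.bmi, "bsa": s.bsa,
            "cardiac_output": s.cardiac_output,
        }
        row.update({f"mass_{k}": v for k, v in s.organ_mass.items()})
        row.update({f"flow_{k}": v for k, v in s.regional_flow.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(
    result: TrialResult,
    subjects: list[IndividualPhysiology],
    outdir: str | Path,
    seed: int,
    constants: SystemConstants | None = None,
) -> dict:
    """Emit the deterministic file set and return the manifest.

    Files: subjects.csv, pk_per_subject.csv, summary.csv, manifest.json.
    The output directory is checked for writability eagerly so a bad path
    fails before any simulation output is lost.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    probe.unlink()

    files: dict[str, str] = {}
    population_frame(subjects).to_csv(outdir / "subjects.csv", index=False)
    result.per_subject.to_csv(outdir / "pk_per_subject.csv", index=False)
    result.summary_frame().to_csv(outdir / "summary.csv", index=False)
    for name in ("subjects.csv", "pk_per_subject.csv", "summary.csv"):
        files[name] = _sha256(outdir / name)

    constants_hash = None
    if constants is not None:
        blob = json.dumps(constants.__dict__, sort_keys=True, default=str)
        constants_hash = hashlib.sha256(blob.encode()).hexdigest()
    manifest = {
        "seed": seed,
        "constants_sha256": constants_hash,
        "n_failed_subjects": result.n_failed,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
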