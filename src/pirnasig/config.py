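"""Run configuration: YAML loading, validation and defaulting."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    max_mm: int = 2
    mirna_max_mm: int = 0
    min_avg: float = 50.0
    te_fold_change: float = 2.0
    gene_fold_change: float = 1.5
    pp_max_offset: int = 30
    max_d: int = 22

    def __post_init__(self) -> None:
        if self.max_mm < 0 or self.mirna_max_mm < 0:
            raise ValueError("mismatch allowances must be >= 0")
        for name in ("min_avg", "te_fold_change", "gene_fold_change",
                     "pp_max_offset", "max_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class LibrarySpec:
    fastq: Path
    library_id: str
    genotype: str
    replicate: int


@dataclass
class RunConfig:
    te_fasta: Path
    mirna_fasta: Path
    rrna_fasta: Path | None
    libraries: list[LibrarySpec]
    out_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0


_TOP_KEYS = {"references", "libraries", "out_dir", "thresholds", "seed"}
_REF_KEYS = {"te", "mirna", "rrna"}
_LIB_KEYS = {"fastq", "library_id", "genotype", "replicate"}
_THRESH_KEYS = {f.name for f in Thresholds.__dataclass_fields__.values()}


class ConfigError(ValueError):
    """Raised for missing files, unknown keys or bad types in a run config."""


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys fail hard; relative paths resolve against the config file's
    directory; referenced input files must exist.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    base = path.parent

    def resolve(p: str, must_exist: bool = True) -> Path:
        resolved = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
        if must_exist and not resolved.exists():
            raise ConfigError(f"referenced file does not exist: {resolved}")
        return resolved

    refs = raw.get("references")
    if not isinstance(refs, dict):
        raise ConfigError("config requires a 'references' mapping")
    _check_keys(refs, _REF_KEYS, "references")
    for key in ("te", "mirna"):
        if key not in refs:
            raise ConfigError(f"references.{key} is required")

    libs_raw = raw.get("libraries")
    if not isinstance(libs_raw, list) or not libs_raw:
        raise ConfigError("config requires a non-empty 'libraries' list")
    libraries: list[LibrarySpec] = []
    seen: set[tuple[str, int]] = set()
    for i, lib in enumerate(libs_raw):
        if not isinstance(lib, dict):
            raise ConfigError(f"libraries[{i}] must be a mapping")
        _check_keys(lib, _LIB_KEYS, f"libraries[{i}]")
        for key in ("fastq", "genotype", "replicate"):
            if key not in lib:
                raise ConfigError(f"libraries[{i}].{key} is required")
        if not isinstance(lib["replicate"], int):
            raise ConfigError(f"libraries[{i}].replicate must be an integer")
        genotype = str(lib["genotype"])
        key = (genotype, lib["replicate"])
        if key in seen:
            raise ConfigError(f"duplicate (genotype, replicate) pair {key}")
        seen.add(key)
        lib_id = str(lib.get("library_id", f"{genotype}_r{lib['replicate']}"))
        libraries.append(
            LibrarySpec(
                fastq=resolve(str(lib["fastq"])),
                library_id=lib_id,
                genotype=genotype,
                replicate=lib["replicate"],
            )
        )

    thresh_raw = raw.get("thresholds", {}) or {}
    if not isinstance(thresh_raw, dict):
        raise ConfigError("'thresholds' must be a mapping")
    _check_keys(thresh_raw, _THRESH_KEYS, "thresholds")
    try:
        thresholds = Thresholds(**thresh_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad thresholds: {exc}") from exc

    if "out_dir" not in raw:
        raise ConfigError("out_dir is required")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")

    return RunConfig(
        te_fasta=resolve(str(refs["te"])),
        mirna_fasta=resolve(str(refs["mirna"])),
        rrna_fasta=resolve(str(refs["rrna"])) if "rrna" in refs else None,
        libraries=libraries,
        out_dir=resolve(str(raw["out_dir"]), must_exist=False),
        thresholds=thresholds,
        seed=seed,
    )
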