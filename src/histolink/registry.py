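"""Model registry and the tissue/stain correspondence table.

The registry holds one :class:`ModelSpec` per deployable deep-learning
model: its task kind (patch-level binary/multiclass classification, or
slide-level MIL classification/survival), output classes, visualization
style, patching geometry, and which backend emulates or runs it. The
correspondence table drives the default deployment mode: when a slide is
digitized, every model registered for its (tissue type, staining)
combination is triggered automatically. Predictive and prognostic models
are flagged on-demand only; the flag is per model so a site can change
the policy by editing the config.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from histolink.errors import ConfigError, ResolutionError

TASK_KINDS = (
    "patch_binary",
    "patch_multiclass",
    "slide_mil_class",
    "slide_mil_survival",
)
VISUALIZATIONS = ("measurement", "color", "density")
PURPOSES = ("tissue", "biomarker", "survival")


@dataclass(frozen=True)
class Patching:
    """Tile geometry: patch edge in pixels at a physical spacing in mpp."""

    patch_size_px: int = 224
    spacing_mpp: float = 1.14


@dataclass(frozen=True)
class RiskConfig:
    """How to turn survival-model logits into a risk score and class."""

    formula_id: str = "logit_sum"
    median_threshold: float = 0.0


@dataclass(frozen=True)
class ModelSpec:
    name: str
    task_kind: str
    classes: tuple[str, ...]
    visualization: str
    backend_id: str = "synthetic"
    target_class: Optional[str] = None
    toolbox: str = "wsinfer"
    builtin: bool = False
    purpose: str = "tissue"
    default_eligible: bool = True
    patching: Patching = field(default_factory=Patching)
    risk: Optional[RiskConfig] = None

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ConfigError(f"{self.name}: unknown task_kind {self.task_kind!r}")
        if self.visualization not in VISUALIZATIONS:
            raise ConfigError(
                f"{self.name}: unknown visualization {self.visualization!r}"
            )
        if self.purpose not in PURPOSES:
            raise ConfigError(f"{self.name}: unknown purpose {self.purpose!r}")
        if not self.classes:
            raise ConfigError(f"{self.name}: classes must be non-empty")
        if self.task_kind == "patch_binary":
            if len(self.classes) not in (1, 2):
                raise ConfigError(
                    f"{self.name}: patch_binary needs 1 or 2 classes"
                )
            if self.target_class is None:
                raise ConfigError(f"{self.name}: patch_binary needs target_class")
        if self.target_class is not None and self.target_class not in self.classes:
            raise ConfigError(
                f"{self.name}: target_class {self.target_class!r} not in classes"
            )
        if self.visualization == "color" and len(self.classes) < 2:
            raise ConfigError(f"{self.name}: color maps need >= 2 classes")
        if self.task_kind == "slide_mil_survival" and self.risk is None:
            raise ConfigError(f"{self.name}: survival models need a risk config")

    @property
    def is_patch_level(self) -> bool:
        return self.task_kind.startswith("patch_")

    @property
    def is_slide_level(self) -> bool:
        return self.task_kind.startswith("slide_")


@dataclass(frozen=True)
class CorrespondenceRow:
    tissue_type: str
    staining: str
    model_name: str


class Registry:
    """Validated model specs plus the default-mode correspondence table."""

    def __init__(
        self,
        specs: list[ModelSpec],
        correspondence: list[CorrespondenceRow],
    ) -> None:
        names = [s.name for s in specs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate model names: {sorted(dupes)}")
        self._specs = {s.name: s for s in specs}
        for row in correspondence:
            if row.model_name not in self._specs:
                raise ConfigError(
                    f"correspondence row ({row.tissue_type}, {row.staining}) "
                    f"references unknown model {row.model_name!r}"
                )
        self._correspondence = list(correspondence)

    @property
    def specs(self) -> list[ModelSpec]:
        return list(self._specs.values())

    @property
    def correspondence(self) -> list[CorrespondenceRow]:
        return list(self._correspondence)

    def __len__(self) -> int:
        return len(self._specs)

    def resolve(self, name: str) -> ModelSpec:
        """Exact-name lookup; unknown names surface as failed attempts."""
        try:
            return self._specs[name]
        except KeyError:
            raise ResolutionError(f"no model named {name!r}") from None

    def lookup_default(self, tissue: str, stain: str) -> list[ModelSpec]:
        """Default-eligible models for a tissue/stain pair.

        Matching is case-insensitive; the result preserves table order and
        is deduplicated. An empty list is a valid outcome (no automatic
        deployment for that combination).
        """
        tissue_l, stain_l = tissue.strip().lower(), stain.strip().lower()
        seen: set[str] = set()
        out: list[ModelSpec] = []
        for row in self._correspondence:
            if (row.tissue_type.lower() == tissue_l
                    and row.staining.lower() == stain_l
                    and row.model_name not in seen):
                spec = self._specs[row.model_name]
                if spec.default_eligible:
                    seen.add(row.model_name)
                    out.append(spec)
        return out


def _spec_from_mapping(entry: dict) -> ModelSpec:
    try:
        patching = Patching(**entry.get("patching", {}))
        risk = RiskConfig(**entry["risk"]) if entry.get("risk") else None
        return ModelSpec(
            name=entry["name"],
            task_kind=entry["task_kind"],
            classes=tuple(entry["classes"]),
            visualization=entry["visualization"],
            backend_id=entry.get("backend_id", "synthetic"),
            target_class=entry.get("target_class"),
            toolbox=entry.get("toolbox", "wsinfer"),
            builtin=bool(entry.get("builtin", False)),
            purpose=entry.get("purpose", "tissue"),
            default_eligible=bool(entry.get("default_eligible", True)),
            patching=patching,
            risk=risk,
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"bad model entry {entry.get('name', entry)!r}: {exc}")


def load_registry(config: Union[str, Path, dict, None] = None) -> Registry:
    """Load a registry from a YAML file, a dict, or the shipped default.

    The shipped default reproduces the 16-model catalogue the framework
    was tested with: 8 built-in patch-level classifiers, 2 custom
    patch-level classifiers, 3 built-in MIL slide classifiers, 2
    attention-MIL biomarker models, and 1 custom MIL tissue classifier.
    """
    if config is None:
        ref = importlib.resources.files("histolink.data") / "registry.yaml"
        data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    elif isinstance(config, dict):
        data = config
    else:
        with open(config, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "models" not in data:
        raise ConfigError("registry config must be a mapping with 'models'")
    specs = [_spec_from_mapping(e) for e in data["models"]]
    rows = [
        CorrespondenceRow(str(r["tissue"]), str(r["stain"]), str(r["model"]))
        for r in data.get("correspondence", [])
    ]
    return Registry(specs, rows)
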