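"""Antibody panel and cohort-design registries.

The panel is the single source of channel semantics for the whole pipeline:
it maps metal tags to marker names and assigns each channel a category
(cell-identity, senescence, SASP, instrument, ...). Cleanup gating, senescence
gating and clustering all look channels up here rather than hard-coding names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "ChannelDescriptor",
    "PanelDefinition",
    "CohortDesign",
    "PanelError",
    "load_panel",
    "write_panel",
    "load_design",
    "write_design",
    "default_panel",
]

#: Valid channel categories. ``identity`` markers drive population clustering;
#: ``senescence``/``sasp``/``dna_damage``/``anti_apoptosis``/``proliferation``
#: form the senescence statistics panel; ``instrument_*`` channels carry
#: acquisition signals (calibration beads, DNA intercalator, viability stain,
#: event length); ``lineage`` channels are used for negative selection.
CATEGORIES = frozenset(
    {
        "identity",
        "senescence",
        "sasp",
        "dna_damage",
        "anti_apoptosis",
        "proliferation",
        "transgene",
        "instrument_bead",
        "instrument_dna",
        "instrument_viability",
        "instrument_event_length",
        "lineage",
    }
)

#: Categories that make up the senescence statistics panel used when
#: sub-clustering p16+ cells.
SENESCENCE_PANEL_CATEGORIES = frozenset(
    {"senescence", "sasp", "dna_damage", "anti_apoptosis", "proliferation"}
)

# Table-1 style capitalization differences ("BCL-2" vs "Bcl-2", "SP7" vs
# "Osterix") collapse onto one canonical marker name.
_ALIASES = {
    "bcl2": "BCL-2",
    "bcl-2": "BCL-2",
    "sp7": "Osterix",
    "osterix": "Osterix",
    "pdgfra": "PDGFRa",
    "cd140a": "PDGFRa",
    "pparg": "PPARg",
    "ppary": "PPARg",
    "yh2a-x": "yH2A-X",
    "yh2ax": "yH2A-X",
    "gh2ax": "yH2A-X",
    "event_length": "Event_length",
    "eventlength": "Event_length",
}


class PanelError(ValueError):
    """Configuration error in a panel, design or rule file."""


def canonical_marker(name: str) -> str:
    """Collapse case/alias variants of a marker name onto one spelling."""
    return _ALIASES.get(name.strip().lower(), name.strip())


@dataclasses.dataclass(frozen=True)
class ChannelDescriptor:
    """One panel channel: a metal tag, the marker it reports, its category."""

    metal_tag: str
    marker: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PanelError(
                f"unknown category {self.category!r} for marker {self.marker!r}; "
                f"valid: {sorted(CATEGORIES)}"
            )


@dataclasses.dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of channels plus a free-form version string."""

    channels: tuple[ChannelDescriptor, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.channels:
            raise PanelError("panel has no channels")
        metals = [c.metal_tag for c in self.channels]
        markers = [c.marker for c in self.channels]
        for seq, what in ((metals, "metal tag"), (markers, "marker")):
            seen: set[str] = set()
            for item in seq:
                if item in seen:
                    raise PanelError(f"duplicate {what} {item!r} in panel")
                seen.add(item)
        for cat in ("instrument_dna", "instrument_viability", "instrument_event_length"):
            if sum(c.category == cat for c in self.channels) > 1:
                raise PanelError(f"category {cat} appears more than once")

    # -- lookups -----------------------------------------------------------
    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    def markers_of(self, *categories: str) -> list[str]:
        return [c.marker for c in self.channels if c.category in categories]

    @property
    def identity_markers(self) -> list[str]:
        return self.markers_of("identity")

    @property
    def senescence_panel_markers(self) -> list[str]:
        return [c.marker for c in self.channels if c.category in SENESCENCE_PANEL_CATEGORIES]

    def instrument_channel(self, category: str) -> str:
        """Marker name of the unique instrument channel of ``category``.

        Raises :class:`PanelError` naming the category when absent.
        """
        hits = self.markers_of(category)
        if not hits:
            raise PanelError(f"panel has no {category} channel")
        return hits[0]

    def resolve(self, name: str) -> str | None:
        """Resolve a file column name to a panel marker, or ``None``.

        Matches marker names (case-insensitively, alias-aware) and metal tags.
        """
        canon = canonical_marker(name)
        lower = canon.lower()
        for c in self.channels:
            if c.marker.lower() == lower or c.metal_tag.lower() == name.strip().lower():
                return c.marker
        return None

    def validate_for_cleanup(self) -> None:
        """Require the instrument channels the cleanup gate depends on."""
        for cat in ("instrument_dna", "instrument_viability", "instrument_event_length"):
            self.instrument_channel(cat)
        if not self.markers_of("instrument_bead"):
            raise PanelError("panel has no instrument_bead channel")


def load_panel(path: str | Path) -> PanelDefinition:
    """Read a panel definition from a YAML/JSON config.

    The file holds ``version`` and a ``channels`` list of mappings with keys
    ``marker``, ``metal`` and ``category``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "channels" not in raw:
        raise PanelError(f"{path}: expected a mapping with a 'channels' list")
    rows = raw["channels"]
    if not rows:
        raise PanelError(f"{path}: empty channel list")
    channels = tuple(
        ChannelDescriptor(
            metal_tag=str(r["metal"]),
            marker=canonical_marker(str(r["marker"])),
            category=str(r["category"]),
        )
        for r in rows
    )
    return PanelDefinition(channels=channels, version=str(raw.get("version", "unversioned")))


def write_panel(panel: PanelDefinition, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "version": panel.version,
        "channels": [
            {"marker": c.marker, "metal": c.metal_tag, "category": c.category}
            for c in panel.channels
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

AGE_GROUPS = ("young", "old")
TREATMENTS = ("none", "vehicle", "senolytic")
GENOTYPES = ("wildtype", "ko_control")

_DESIGN_COLUMNS = ["sample_id", "age_group", "treatment", "genotype", "file_path"]


@dataclasses.dataclass(frozen=True)
class CohortDesign:
    """Sample sheet: one row per animal with group, treatment and genotype."""

    samples: pd.DataFrame  # columns = _DESIGN_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.samples.columns]
        if missing:
            raise PanelError(f"cohort design missing columns {missing}")
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise PanelError(f"duplicate sample_id {dup!r} in cohort design")
        for col, valid in (
            ("age_group", AGE_GROUPS),
            ("treatment", TREATMENTS),
            ("genotype", GENOTYPES),
        ):
            bad = set(self.samples[col]) - set(valid)
            if bad:
                raise PanelError(f"invalid {col} value(s) {sorted(bad)}; valid: {valid}")

    @staticmethod
    def from_rows(rows: Iterable[tuple[str, str, str, str, str]]) -> "CohortDesign":
        return CohortDesign(pd.DataFrame(list(rows), columns=_DESIGN_COLUMNS))

    def group_of(self, sample_id: str) -> str:
        """Simulation/analysis group: young, old, or old_senolytic."""
        row = self.samples.set_index("sample_id").loc[sample_id]
        return design_group(row["age_group"], row["treatment"])

    @property
    def analysis_samples(self) -> pd.DataFrame:
        """Rows entering cohort statistics (knock-out controls excluded)."""
        return self.samples[self.samples["genotype"] != "ko_control"].reset_index(drop=True)

    def sample_ids(self, group: str | None = None, include_controls: bool = False) -> list[str]:
        df = self.samples if include_controls else self.analysis_samples
        if group is not None:
            keep = [
                design_group(a, t) == group
                for a, t in zip(df["age_group"], df["treatment"])
            ]
            df = df[keep]
        return list(df["sample_id"])


def design_group(age_group: str, treatment: str) -> str:
    if age_group == "old" and treatment == "senolytic":
        return "old_senolytic"
    return age_group


def load_design(path: str | Path) -> CohortDesign:
    """Read a cohort design TSV (header sample_id, age_group, treatment, genotype, file_path)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return CohortDesign(df)


def write_design(design: CohortDesign, path: str | Path) -> Path:
    path = Path(path)
    design.samples.to_csv(path, sep="\t", index=False)
    return path


def default_panel() -> PanelDefinition:
    """The full antibody panel shipped with the package."""
    from . import resources

    return resources.default_panel()
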