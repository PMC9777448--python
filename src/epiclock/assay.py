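"""Targeted-assay definition: genomic regions, Infinium anchor probes, CpG units.

The packaged default describes a six-amplicon EpiTYPER panel anchored on seven
Infinium probes (in *ELOVL2*, *NHLRC1*, *SIRT7/MAFG*, *AIM2*, *EDARADD* and
*TFAP2E*) covering 70 assessable CpG units in total.  Coordinates are stored
exactly as designed: 1-based, inclusive, on GRCh37/hg19.  CpG units are not
assigned genomic positions; they are identified positionally per region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

ASSEMBLY = "GRCh37/hg19"

__all__ = [
    "GenomicRegion",
    "ProbeAnchor",
    "TargetRegion",
    "AssayDefinition",
    "AssayValidationError",
    "load_assay_definition",
    "write_assay_definition",
    "validate_assay",
    "expected_unit_ids",
]


class AssayValidationError(ValueError):
    """An assay definition violates a structural invariant."""


@dataclass(frozen=True)
class GenomicRegion:
    """A closed genomic interval, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    assembly: str = ASSEMBLY

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AssayValidationError("chromosome name must be non-empty")
        if self.start > self.end:
            raise AssayValidationError(
                f"region {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.assembly != ASSEMBLY:
            raise AssayValidationError(
                f"unsupported assembly {self.assembly!r}; expected {ASSEMBLY!r}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProbeAnchor:
    """An Infinium probe (cg-number) with its genomic coordinate."""

    probe_id: str
    chrom: str
    pos: int


@dataclass(frozen=True)
class TargetRegion:
    """One amplicon of the targeted assay: a region plus its anchor probes."""

    gene_label: str
    region: GenomicRegion
    probes: tuple[ProbeAnchor, ...]
    n_cpg_units: int

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes)


@dataclass(frozen=True)
class AssayDefinition:
    """A named collection of target regions forming one targeted clock assay."""

    regions: tuple[TargetRegion, ...]
    name: str = "custom"
    version: str = "0"

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_probes(self) -> int:
        return sum(len(r.probes) for r in self.regions)

    @property
    def n_cpg_units(self) -> int:
        return sum(r.n_cpg_units for r in self.regions)


def _unit_key(gene_label: str) -> str:
    """Sanitize a gene label into an identifier stem (SIRT7/MAFG -> SIRT7_MAFG)."""
    return re.sub(r"[^0-9A-Za-z]+", "_", gene_label).strip("_")


def validate_assay(assay: AssayDefinition) -> list[str]:
    """Check structural invariants; return a list of human-readable violations.

    An empty list means the definition is valid.  Checked rules: unique region
    labels, positive unit counts, at least one probe per region, probe
    coordinates contained in their region, and no overlap between regions on
    the same chromosome.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for reg in assay.regions:
        label = reg.gene_label
        if label in seen:
            violations.append(f"{label}: duplicate region label")
        seen.add(label)
        if reg.n_cpg_units <= 0:
            violations.append(f"{label}: n_cpg_units must be positive")
        if not reg.probes:
            violations.append(f"{label}: region has no anchor probes")
        for probe in reg.probes:
            if not reg.region.contains(probe.chrom, probe.pos):
                violations.append(
                    f"{label}: probe {probe.probe_id} at {probe.chrom}:{probe.pos} "
                    f"falls outside {reg.region.chrom}:{reg.region.start}-{reg.region.end}"
                )
    for i, a in enumerate(assay.regions):
        for b in assay.regions[i + 1 :]:
            if a.region.overlaps(b.region):
                violations.append(
                    f"{a.gene_label}/{b.gene_label}: regions overlap on {a.region.chrom}"
                )
    return violations


def expected_unit_ids(assay: AssayDefinition) -> list[str]:
    """Deterministic CpG-unit identifiers, ``<gene>_unit<k>`` with k = 1..n.

    Regions are emitted in definition order; the result is injective as long
    as region labels are unique (a validated invariant).
    """
    ids: list[str] = []
    for reg in assay.regions:
        stem = _unit_key(reg.gene_label)
        ids.extend(f"{stem}_unit{k}" for k in range(1, reg.n_cpg_units + 1))
    return ids


def _parse_definition(doc: dict, source: str) -> AssayDefinition:
    try:
        regions = []
        for rd in doc["regions"]:
            region = GenomicRegion(
                chrom=str(rd["chrom"]),
                start=int(rd["start"]),
                end=int(rd["end"]),
                assembly=str(doc.get("assembly", ASSEMBLY)),
            )
            probes = tuple(
                ProbeAnchor(str(p["id"]), str(p["chrom"]), int(p["pos"]))
                for p in rd["probes"]
            )
            regions.append(
                TargetRegion(
                    gene_label=str(rd["gene_label"]),
                    region=region,
                    probes=probes,
                    n_cpg_units=int(rd["n_cpg_units"]),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, AssayValidationError):
            raise
        raise AssayValidationError(f"{source}: malformed assay definition: {exc}") from exc
    assay = AssayDefinition(
        regions=tuple(regions),
        name=str(doc.get("name", "custom")),
        version=str(doc.get("version", "0")),
    )
    violations = validate_assay(assay)
    if violations:
        raise AssayValidationError(f"{source}: " + "; ".join(violations))
    return assay


def load_assay_definition(path: str | Path | None = None) -> AssayDefinition:
    """Load and validate an assay definition from YAML; ``None`` loads the default.

    Raises
    ------
    AssayValidationError
        If the file is malformed or violates a structural invariant.
    """
    if path is None:
        text = (
            resources.files("epiclock").joinpath("data/default_assay.yaml").read_text()
        )
        source = "<default assay>"
    else:
        text = Path(path).read_text()
        source = str(path)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise AssayValidationError(f"{source}: cannot parse YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise AssayValidationError(f"{source}: expected a mapping at top level")
    return _parse_definition(doc, source)


def write_assay_definition(assay: AssayDefinition, path: str | Path) -> None:
    """Serialize a definition to YAML; round-trips through the loader."""
    doc = {
        "name": assay.name,
        "version": assay.version,
        "assembly": ASSEMBLY,
        "regions": [
            {
                "gene_label": reg.gene_label,
                "chrom": reg.region.chrom,
                "start": reg.region.start,
                "end": reg.region.end,
                "n_cpg_units": reg.n_cpg_units,
                "probes": [
                    {"id": p.probe_id, "chrom": p.chrom, "pos": p.pos}
                    for p in reg.probes
                ],
            }
            for reg in assay.regions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def to_bed(assay: AssayDefinition) -> str:
    """BED text for the target regions (0-based half-open, converted from the
    1-based inclusive internal coordinates) for genome-browser use."""
    lines = [
        f"{r.region.chrom}\t{r.region.start - 1}\t{r.region.end}\t{_unit_key(r.gene_label)}"
        for r in assay.regions
    ]
    return "\n".join(lines) + "\n"
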