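"""Analysis configuration (``.ini``) parsing and custom allele binning.

The configuration file is INI-syntax with ``;;`` full-line comments.  Regular
sections (``[HardyWeinberg]``, ``[EwensWatterson]``, ``[Haplotypes]``,
``[Linkage]``, ...) hold ``key = value`` options selecting analyses and their
parameters.  One special section, ``[CustomBinning]``, groups allele names
into user-defined categories (G-groups, supertypes, TCE groups, NMDP codes,
or anything else) before analysis.

CustomBinning grammar, per locus::

    [CustomBinning]
    DRB1 = !11AD/11:01/11:04
     !13XX/13:01/13:02
    DQB1 = !G1/06:01/06:02

Each group starts with ``!`` followed by the group identifier and member
alleles, all delimited by ``/``.  Groups after the first for a locus appear on
continuation lines beginning with whitespace.  A continuation line that does
not start with ``!`` extends the member list of the previous group.  When the
filter is applied, every member allele in the dataset is converted to its
group identifier; everything else passes through unchanged.
"""

from __future__ import annotations

import configparser
import io
import warnings
from dataclasses import dataclass, field
from typing import IO

from .dataio import PopulationDataset

KNOWN_SECTIONS = {
    "General",
    "HardyWeinberg",
    "EwensWatterson",
    "Haplotypes",
    "Linkage",
    "CustomBinning",
    "Simulation",
}

__all__ = [
    "ConfigError",
    "BinningConflictError",
    "BinningFilter",
    "AnalysisConfig",
    "parse_config",
    "apply_binning",
]


class ConfigError(ValueError):
    """Raised for malformed configuration input."""


class BinningConflictError(ConfigError):
    """Raised when an allele is claimed by two groups at the same locus."""


@dataclass
class BinningFilter:
    """Per-locus allele grouping rules: ``rules[locus]`` is a list of
    ``(group_identifier, member_alleles)`` pairs.

    Allele matching is case-sensitive and exact; within one locus no allele
    may belong to two groups.
    """

    rules: dict[str, list[tuple[str, tuple[str, ...]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, groups in self.rules.items():
            seen: dict[str, str] = {}
            for gid, members in groups:
                if not gid:
                    raise ConfigError(f"empty group identifier at locus {locus!r}")
                if not members:
                    raise ConfigError(f"group {gid!r} at locus {locus!r} has no members")
                for m in members:
                    if m in seen:
                        raise BinningConflictError(
                            f"allele {m!r} at locus {locus!r} appears in groups "
                            f"{seen[m]!r} and {gid!r}"
                        )
                    seen[m] = gid

    def mapping(self) -> dict[str, dict[str, str]]:
        """``{locus: {member_allele: group_identifier}}`` lookup table."""
        out: dict[str, dict[str, str]] = {}
        for locus, groups in self.rules.items():
            table: dict[str, str] = {}
            for gid, members in groups:
                for m in members:
                    table[m] = gid
            out[locus] = table
        return out

    @property
    def loci(self) -> list[str]:
        return list(self.rules)


@dataclass
class AnalysisConfig:
    """Parsed configuration: raw sections plus typed accessors.

    Unknown sections are preserved verbatim and listed in
    ``unknown_sections`` so callers can warn without losing information.
    """

    sections: dict[str, dict[str, str]]
    binning: BinningFilter | None = None

    @property
    def unknown_sections(self) -> list[str]:
        return [s for s in self.sections if s not in KNOWN_SECTIONS]

    def get(self, section: str, key: str, default: str | None = None) -> str | None:
        return self.sections.get(section, {}).get(key, default)

    def getint(self, section: str, key: str, default: int) -> int:
        raw = self.get(section, key)
        if raw is None:
            return default
        try:
            return int(raw)
        except ValueError:
            raise ConfigError(f"[{section}] {key} = {raw!r} is not an integer") from None

    def getfloat(self, section: str, key: str, default: float) -> float:
        raw = self.get(section, key)
        if raw is None:
            return default
        try:
            return float(raw)
        except ValueError:
            raise ConfigError(f"[{section}] {key} = {raw!r} is not a number") from None

    def getbool(self, section: str, key: str, default: bool) -> bool:
        raw = self.get(section, key)
        if raw is None:
            return default
        low = raw.strip().lower()
        if low in {"1", "true", "yes", "on"}:
            return True
        if low in {"0", "false", "no", "off"}:
            return False
        raise ConfigError(f"[{section}] {key} = {raw!r} is not a boolean")

    # -- analysis selection -------------------------------------------------
    @property
    def hwe_chisq_enabled(self) -> bool:
        return self.getbool("HardyWeinberg", "chisq", "HardyWeinberg" in self.sections)

    @property
    def hwe_exact_enabled(self) -> bool:
        return self.getbool("HardyWeinberg", "exact", "HardyWeinberg" in self.sections)

    @property
    def ewens_watterson_enabled(self) -> bool:
        return "EwensWatterson" in self.sections

    @property
    def haplotypes_enabled(self) -> bool:
        return "Haplotypes" in self.sections

    @property
    def untyped_marker(self) -> str:
        return self.get("General", "untypedAllele", "****")

    def seed(self, default: int = 0) -> int:
        return self.getint("General", "seed", default)

    def haplotype_locus_sets(self, loci: list[str]) -> list[tuple[str, ...]]:
        """Locus sets for haplotype estimation.

        ``[Haplotypes] loci`` is a comma-separated list of sets, loci within a
        set joined by ``:`` (locus names never contain colons).  The literal
        value ``all-pairs`` (also ``[Linkage] all-pairs = yes``) expands to
        every unordered pair in dataset order.
        """
        raw = self.get("Haplotypes", "loci", "")
        sets: list[tuple[str, ...]] = []
        for chunk in raw.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            if chunk == "all-pairs":
                sets.extend(_all_pairs(loci))
                continue
            names = tuple(x.strip() for x in chunk.split(":"))
            for name in names:
                if name not in loci:
                    raise ConfigError(f"[Haplotypes] unknown locus {name!r}")
            if len(names) < 2:
                raise ConfigError(f"[Haplotypes] locus set {chunk!r} needs >= 2 loci")
            sets.append(names)
        if self.getbool("Haplotypes", "all-pairs", False):
            for pair in _all_pairs(loci):
                if pair not in sets:
                    sets.append(pair)
        return sets

    def linkage_pairs(self, loci: list[str]) -> list[tuple[str, str]]:
        if "Linkage" not in self.sections:
            return []
        raw = self.get("Linkage", "pairs", "all-pairs")
        if raw.strip() == "all-pairs":
            return _all_pairs(loci)
        pairs: list[tuple[str, str]] = []
        for chunk in raw.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            names = tuple(x.strip() for x in chunk.split(":"))
            if len(names) != 2:
                raise ConfigError(f"[Linkage] pair {chunk!r} must name exactly 2 loci")
            for name in names:
                if name not in loci:
                    raise ConfigError(f"[Linkage] unknown locus {name!r}")
            pairs.append(names)  # type: ignore[arg-type]
        return pairs

    @property
    def ld_permutations(self) -> int:
        return self.getint("Linkage", "permutations", 0)


def _all_pairs(loci: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(loci) for b in loci[i + 1 :]]


def parse_config(source: str | IO[str]) -> AnalysisConfig:
    """Parse an ``.ini`` stream (or literal string) into an :class:`AnalysisConfig`.

    ``;;`` comment lines are stripped everywhere.  The ``[CustomBinning]``
    section is parsed with its own grammar (see module docstring); all other
    sections go through :mod:`configparser`.
    """
    if not isinstance(source, str):
        source = source.read()
    plain_lines: list[str] = []
    binning_lines: list[tuple[int, str]] = []
    in_binning = False
    for lineno, line in enumerate(source.splitlines(), start=1):
        if line.lstrip().startswith(";;"):
            continue
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            in_binning = stripped[1:-1].strip() == "CustomBinning"
            if not in_binning:
                plain_lines.append(line)
            continue
        if in_binning:
            if stripped:
                binning_lines.append((lineno, line))
        else:
            plain_lines.append(line)

    parser = configparser.ConfigParser(
        interpolation=None, delimiters=("=", ":"), strict=True
    )
    parser.optionxform = str  # preserve key case (locus names, camelCase keys)
    try:
        parser.read_string("\n".join(plain_lines))
    except configparser.Error as exc:
        raise ConfigError(f"malformed configuration: {exc}") from exc

    sections = {name: dict(parser[name]) for name in parser.sections()}
    binning = _parse_binning(binning_lines) if binning_lines else None
    if binning is not None:
        sections["CustomBinning"] = {locus: "" for locus in binning.loci}

    for name in sections:
        if name not in KNOWN_SECTIONS:
            warnings.warn(f"unknown configuration section [{name}] preserved", stacklevel=2)
    return AnalysisConfig(sections=sections, binning=binning)


def _parse_binning(lines: list[tuple[int, str]]) -> BinningFilter:
    rules: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    locus: str | None = None
    for lineno, raw in lines:
        continuation = raw[:1] in (" ", "\t")
        text = raw.strip()
        if not continuation:
            # "<locus> = !id/member/..." or "<locus>: !id/..."
            for delim in ("=", ":"):
                if delim in text:
                    key, _, rest = text.partition(delim)
                    break
            else:
                raise ConfigError(
                    f"line {lineno}: expected '<locus> = !group/...' in [CustomBinning]"
                )
            locus = key.strip()
            if not locus:
                raise ConfigError(f"line {lineno}: empty locus name in [CustomBinning]")
            rules.setdefault(locus, [])
            text = rest.strip()
            if not text:
                continue  # groups may all be on continuation lines
            if not text.startswith("!"):
                raise ConfigError(
                    f"line {lineno}: first group for locus {locus!r} must start with '!'"
                )
        if locus is None:
            raise ConfigError(f"line {lineno}: group line before any locus in [CustomBinning]")
        if text.startswith("!"):
            parts = [p for p in text[1:].split("/") if p != ""]
            if len(parts) < 2:
                raise ConfigError(
                    f"line {lineno}: group needs an identifier and >= 1 member allele"
                )
            rules[locus].append((parts[0], tuple(parts[1:])))
        else:
            # continuation of the previous group's member list
            if not rules[locus]:
                raise ConfigError(
                    f"line {lineno}: first group for locus {locus!r} must start with '!'"
                )
            gid, members = rules[locus][-1]
            extra = tuple(p for p in text.split("/") if p != "")
            rules[locus][-1] = (gid, members + extra)
    return BinningFilter(rules=rules)  # validates conflicts


def apply_binning(dataset: PopulationDataset, filt: BinningFilter) -> PopulationDataset:
    """Return a new dataset with member alleles replaced by group identifiers.

    Filter loci absent from the dataset are ignored with a warning; alleles
    not in any group, and untyped alleles, pass through unchanged.  The input
    dataset is not modified.
    """
    extra = [locus for locus in filt.loci if locus not in dataset.loci]
    if extra:
        warnings.warn(
            f"binning filter loci not in dataset, ignored: {', '.join(extra)}",
            stacklevel=2,
        )
    mapping = {k: v for k, v in filt.mapping().items() if k in dataset.loci}
    return dataset.replace_alleles(mapping)
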