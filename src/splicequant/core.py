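"""Domain types shared by every pipeline stage.

The locus under study carries two alternatively spliced exons between two
constitutive flanks.  Following the field's nomenclature the exons are called
``M`` ("medium") and ``L`` ("little"), and a splice form is named by its
inclusion pattern: ``0-0`` (neither), ``M-0``, ``0-L`` and ``M-L``.  A
separately amplified endogenous control gene (GUSB) travels through the same
library and serves as normalisation denominator.

This module defines the amplicon design (exon segments, the 16 internal
8-nt barcodes, primers, control sequence), splice-form identifiers, sample
metadata, the per-sample count table, and template construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpliceForm",
    "SegmentRole",
    "ExonSegment",
    "AmpliconDesign",
    "SampleMetadata",
    "SpliceFormCountTable",
    "DesignError",
    "Read",
    "ReadPair",
    "build_templates",
    "default_design",
    "reverse_complement",
    "read_fastq",
    "write_fastq",
]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N tolerated, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class DesignError(ValueError):
    """Raised when an amplicon design violates its invariants."""


class SpliceForm(enum.StrEnum):
    """Splice-form identifiers; string values follow the locus nomenclature."""

    NULL = "0-0"          # neither alternative exon included
    M_ONLY = "M-0"        # exon M only
    BOTH = "M-L"          # both alternative exons
    L_ONLY = "0-L"        # exon L only
    CONTROL = "GUSB"      # endogenous control amplicon
    UNASSIGNED = "UNASSIGNED"

    @property
    def has_m(self) -> bool:
        return self in (SpliceForm.M_ONLY, SpliceForm.BOTH)

    @property
    def has_l(self) -> bool:
        return self in (SpliceForm.L_ONLY, SpliceForm.BOTH)


#: The four region-of-interest splice forms, in canonical order.
ROI_FORMS: tuple[SpliceForm, ...] = (
    SpliceForm.NULL,
    SpliceForm.M_ONLY,
    SpliceForm.BOTH,
    SpliceForm.L_ONLY,
)

#: ROI forms plus the endogenous control — every species that can be counted.
ALL_SPECIES: tuple[SpliceForm, ...] = ROI_FORMS + (SpliceForm.CONTROL,)


class SegmentRole(enum.StrEnum):
    CONST_LEFT = "constitutive_left"
    ALT_M = "alternative_M"
    ALT_L = "alternative_L"
    CONST_RIGHT = "constitutive_right"


@dataclass(frozen=True)
class ExonSegment:
    """One exonic segment of the amplicon design."""

    name: str
    sequence: str
    role: SegmentRole

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise DesignError(f"segment {self.name!r}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise DesignError(
                f"segment {self.name!r}: non-ACGT characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class Read:
    """A single sequencing read (sequence plus phred-33 quality string)."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )


@dataclass
class ReadPair:
    """A read pair; ``r2 is None`` marks single-end data."""

    r1: Read
    r2: Read | None = None

    @property
    def is_paired(self) -> bool:
        return self.r2 is not None


@dataclass
class AmpliconDesign:
    """The locus blueprint: segments, barcodes, primers and control.

    ``species_lengths``, when provided, is checked against the constructed
    template lengths; the mapping of gBlock spike-in lengths to species is
    carried explicitly because it is a property of the ordered synthetic
    fragments, not derivable from the locus.
    """

    segments: dict[SegmentRole, ExonSegment]
    barcodes: list[str]
    forward_primer: str = ""
    reverse_primer: str = ""
    control_sequence: str = ""
    quatromer_length: int = 4
    species_lengths: dict[SpliceForm, int] | None = None

    def __post_init__(self) -> None:
        self.barcodes = [b.upper() for b in self.barcodes]
        self.control_sequence = self.control_sequence.upper()
        self.forward_primer = self.forward_primer.upper()
        self.reverse_primer = self.reverse_primer.upper()
        self.validate()

    def validate(self) -> None:
        for role in SegmentRole:
            if role not in self.segments:
                raise DesignError(f"design is missing segment role {role.value!r}")
            if self.segments[role].role is not role:
                raise DesignError(
                    f"segment stored under role {role.value!r} declares role "
                    f"{self.segments[role].role.value!r}"
                )
        if not self.barcodes:
            raise DesignError("design has an empty barcode list")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise DesignError(f"barcodes have mixed lengths {sorted(lengths)}")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise DesignError("barcodes are not pairwise distinct")
        for b in self.barcodes:
            if set(b) - DNA_ALPHABET:
                raise DesignError(f"barcode {b!r} contains non-ACGT characters")
        if self.control_sequence and set(self.control_sequence) - DNA_ALPHABET:
            raise DesignError("control sequence contains non-ACGT characters")
        if self.quatromer_length < 0:
            raise DesignError("quatromer_length must be >= 0")
        if self.species_lengths:
            templates = build_templates(self)
            for form, expected in self.species_lengths.items():
                form = SpliceForm(form)
                got = len(templates[form])
                if got != expected:
                    raise DesignError(
                        f"template for {form} has length {got}, design "
                        f"declares {expected}"
                    )

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0])

    @property
    def n_samples(self) -> int:
        return len(self.barcodes)

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": {
                role.value: {"name": seg.name, "sequence": seg.sequence}
                for role, seg in self.segments.items()
            },
            "barcodes": list(self.barcodes),
            "forward_primer": self.forward_primer,
            "reverse_primer": self.reverse_primer,
            "control_sequence": self.control_sequence,
            "quatromer_length": self.quatromer_length,
            "species_lengths": (
                {str(k): v for k, v in self.species_lengths.items()}
                if self.species_lengths
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AmpliconDesign":
        segments = {}
        for role_str, seg in d["segments"].items():
            role = SegmentRole(role_str)
            segments[role] = ExonSegment(
                name=seg.get("name", role_str), sequence=seg["sequence"], role=role
            )
        lengths = d.get("species_lengths")
        return cls(
            segments=segments,
            barcodes=list(d["barcodes"]),
            forward_primer=d.get("forward_primer", ""),
            reverse_primer=d.get("reverse_primer", ""),
            control_sequence=d.get("control_sequence", ""),
            quatromer_length=int(d.get("quatromer_length", 4)),
            species_lengths=(
                {SpliceForm(k): int(v) for k, v in lengths.items()}
                if lengths
                else None
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmpliconDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_templates(design: AmpliconDesign) -> dict[SpliceForm, str]:
    """Construct the four ROI splice-form templates plus the control.

    Template for form *f* is the concatenation
    ``CONST_LEFT + (M if f includes M) + (L if f includes L) + CONST_RIGHT``.
    Deterministic: the same design always yields identical strings.
    """
    try:
        cl = design.segments[SegmentRole.CONST_LEFT].sequence
        m = design.segments[SegmentRole.ALT_M].sequence
        l = design.segments[SegmentRole.ALT_L].sequence
        cr = design.segments[SegmentRole.CONST_RIGHT].sequence
    except KeyError as exc:  # pragma: no cover - validate() normally catches this
        raise DesignError(f"design is missing segment role {exc.args[0]}") from exc
    templates = {
        SpliceForm.NULL: cl + cr,
        SpliceForm.M_ONLY: cl + m + cr,
        SpliceForm.BOTH: cl + m + l + cr,
        SpliceForm.L_ONLY: cl + l + cr,
    }
    if design.control_sequence:
        templates[SpliceForm.CONTROL] = design.control_sequence
    return templates


@dataclass
class SampleMetadata:
    """Covariates carried per sample (the statistical models consuming them
    are out of this package's hands)."""

    sample_id: str
    pool_id: str = ""
    group: str = ""
    age: float | None = None
    sex: str = "unknown"
    rin: float | None = None
    pmi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        if self.rin is not None and not (1.0 <= self.rin <= 10.0):
            raise ValueError(f"RIN must be in [1, 10], got {self.rin}")


class SpliceFormCountTable:
    """Per-sample, per-species read counts.

    Backed by a tidy :class:`pandas.DataFrame` with columns
    ``sample_id, species, raw_count, normalized_count, corrected``.
    ``normalized_count`` is NaN until a normalisation or bias-correction
    stage fills it.
    """

    COLUMNS = ["sample_id", "species", "raw_count", "normalized_count", "corrected"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"count table is missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        df["raw_count"] = df["raw_count"].astype(np.int64)
        if (df["raw_count"] < 0).any():
            raise ValueError("raw counts must be non-negative")
        norm = df["normalized_count"].astype(float)
        if (norm.dropna() < 0).any():
            raise ValueError("normalized counts must be non-negative")
        df["normalized_count"] = norm
        df["corrected"] = df["corrected"].astype(bool)
        if df.duplicated(["sample_id", "species"]).any():
            raise ValueError("duplicate (sample_id, species) rows")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[SpliceForm | str, int]]
    ) -> "SpliceFormCountTable":
        """Build from ``{sample_id: {species: count}}`` nested mappings."""
        rows = []
        for sample_id, per_species in counts.items():
            for species, n in per_species.items():
                rows.append(
                    {
                        "sample_id": sample_id,
                        "species": str(SpliceForm(species)),
                        "raw_count": int(n),
                        "normalized_count": np.nan,
                        "corrected": False,
                    }
                )
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def counts_for(self, sample_id: str) -> dict[str, int]:
        sub = self.df[self.df["sample_id"] == sample_id]
        return dict(zip(sub["species"], sub["raw_count"]))

    def totals(self, include_unassigned: bool = True) -> pd.Series:
        """Total raw reads per sample."""
        df = self.df
        if not include_unassigned:
            df = df[df["species"] != str(SpliceForm.UNASSIGNED)]
        return df.groupby("sample_id")["raw_count"].sum()

    def shares(self, roi_only: bool = True, corrected: bool = False) -> pd.DataFrame:
        """Per-sample species fractions among assigned reads.

        With ``roi_only`` the denominator is the four ROI forms (the control
        and unassigned reads are excluded); with ``corrected`` the
        normalized/corrected column is used instead of raw counts.
        """
        value_col = "normalized_count" if corrected else "raw_count"
        keep = [str(f) for f in (ROI_FORMS if roi_only else ALL_SPECIES)]
        sub = self.df[self.df["species"].isin(keep)].copy()
        denom = sub.groupby("sample_id")[value_col].transform("sum")
        sub["share"] = sub[value_col] / denom
        return sub[["sample_id", "species", "share"]].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpliceFormCountTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpliceFormCountTable):
            return NotImplemented
        return self.df.equals(other.df)


# ---- FASTQ I/O ---------------------------------------------------------
#
# Parsing goes through Biopython's fast FastqGeneralIterator; writing is the
# standard 4-line record layout.

def read_fastq(path: str | Path) -> list[Read]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    reads = []
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(Read(id=title.split()[0], seq=seq, qual=qual))
    return reads


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---- Default synthetic design ------------------------------------------
#
# The exact exon and control sequences of the real locus are not public, so
# the default design is synthetic.  It reproduces the experiment's geometry:
# 16 internal 8-nt barcodes (pairwise edit distance >= 3), 4-nt quatromers,
# and five amplicon species whose lengths are the five gBlock lengths
# 125/156/210/219/273 bp under the unique additive assignment
# (GUSB=125, 0-0=156, 0-L=210, M-0=219, M-L=273; M=63 nt, L=54 nt).
# Sequences were fixed once such that junction probes are discriminative, no
# barcode occurs within edit distance 1 of any template on either strand, and
# no single-substitution variant of a barcode — including shifted windows
# borrowing quatromer or amplicon context bases — coincides with a different
# barcode, so fuzzy demultiplexing at one allowed error cannot cross-assign
# singly-corrupted reads.

_DEFAULT_BARCODES = [
    "CGGAGCCT", "GTTCCTGT", "ACCATTAT", "TCACAAGG",
    "CCATAGTT", "CGGATGAG", "TACAATAT", "CGTATCGT",
    "GAGAATGT", "CCCGGTAA", "GTGGGCTA", "GTTGTTAG",
    "CCCAAGAG", "CTTCAAAG", "CGTAGTAA", "ACAACTGT",
]

_DEFAULT_CONST_LEFT = (
    "GAATAGTTGATTATTCGTCACGGCTACGCGGAGGTGATCTGAGCCGTAGACGATGAATTCGTTTGTCCTACCAATTCGAC"
)
_DEFAULT_M = "TGCAGGTTAGGGCCCGTATCAAGGTACGTTTAAGTGATTGCCTATGACATTACGGTCCTCTTA"
_DEFAULT_L = "GTTTAGCGGTTTAGAGCCGACCTGCAGGAGACCTTCCGCCCGTAGTCTTGAGCA"
_DEFAULT_CONST_RIGHT = (
    "AGGGCGTCGTGTATGCACGAAACATGCTAATACGAAGCGCACCCAACACGTAACTGGGATGTGTTGGGATGACCGT"
)
_DEFAULT_CONTROL = (
    "ATGCCTAATCATGTGTGCCACAGGGTCTAAGTGCAAGATAGGTCATATCAGCCGCCTGCCATCGTCGATCGGCAGT"
    "ATCAATTTGAGTCCACGAGAACACGAGTCTCAGATTCCTTACAGAGATA"
)


def default_design() -> AmpliconDesign:
    """The built-in synthetic 16-plex design (see module docstring)."""
    segments = {
        SegmentRole.CONST_LEFT: ExonSegment(
            "CONST_LEFT", _DEFAULT_CONST_LEFT, SegmentRole.CONST_LEFT
        ),
        SegmentRole.ALT_M: ExonSegment("M", _DEFAULT_M, SegmentRole.ALT_M),
        SegmentRole.ALT_L: ExonSegment("L", _DEFAULT_L, SegmentRole.ALT_L),
        SegmentRole.CONST_RIGHT: ExonSegment(
            "CONST_RIGHT", _DEFAULT_CONST_RIGHT, SegmentRole.CONST_RIGHT
        ),
    }
    return AmpliconDesign(
        segments=segments,
        barcodes=list(_DEFAULT_BARCODES),
        forward_primer=_DEFAULT_CONST_LEFT[:22],
        reverse_primer=reverse_complement(_DEFAULT_CONST_RIGHT[-22:]),
        control_sequence=_DEFAULT_CONTROL,
        quatromer_length=4,
        species_lengths={
            SpliceForm.CONTROL: 125,
            SpliceForm.NULL: 156,
            SpliceForm.L_ONLY: 210,
            SpliceForm.M_ONLY: 219,
            SpliceForm.BOTH: 273,
        },
    )
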