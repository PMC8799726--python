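"""Splice-form classification of merged reads by diagnostic junction probes.

The four splice forms of the region of interest share both constitutive
flanks, and the alternative exons themselves can be homologous with
flanking sequence — full-template identity is therefore the wrong signal.
Instead each form is recognised by the exon *junctions* it alone realises:

======  =================================
form    junctions present
======  =================================
0-0     CONST_LEFT|CONST_RIGHT
M-0     CONST_LEFT|M, M|CONST_RIGHT
M-L     CONST_LEFT|M, M|L, L|CONST_RIGHT
0-L     CONST_LEFT|L, L|CONST_RIGHT
======  =================================

A probe spans ``flank`` bases on each side of its junction (20 nt by
default).  A read is called as form *f* iff every probe of *f* hits (edit
distance anywhere in the read <= ``floor(max_error_rate * probe_length)``)
and no probe exclusive to a different form hits.  Conflicts — chimeric PCR
products hitting junctions of two forms — are deliberately UNASSIGNED
rather than majority-voted, so they cannot inflate rare forms.  The
endogenous control is recognised by a probe from the control amplicon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .core import (
    ALL_SPECIES,
    AmpliconDesign,
    DesignError,
    Read,
    SegmentRole,
    SpliceForm,
    SpliceFormCountTable,
    build_templates,
    reverse_complement,
)

__all__ = [
    "DiagnosticSet",
    "build_diagnostics",
    "classify_read",
    "count_splice_forms",
]

#: junction name -> (left role, right role)
_JUNCTIONS: dict[str, tuple[SegmentRole, SegmentRole]] = {
    "CL|M": (SegmentRole.CONST_LEFT, SegmentRole.ALT_M),
    "CL|L": (SegmentRole.CONST_LEFT, SegmentRole.ALT_L),
    "CL|CR": (SegmentRole.CONST_LEFT, SegmentRole.CONST_RIGHT),
    "M|L": (SegmentRole.ALT_M, SegmentRole.ALT_L),
    "M|CR": (SegmentRole.ALT_M, SegmentRole.CONST_RIGHT),
    "L|CR": (SegmentRole.ALT_L, SegmentRole.CONST_RIGHT),
}

_FORM_JUNCTIONS: dict[SpliceForm, tuple[str, ...]] = {
    SpliceForm.NULL: ("CL|CR",),
    SpliceForm.M_ONLY: ("CL|M", "M|CR"),
    SpliceForm.BOTH: ("CL|M", "M|L", "L|CR"),
    SpliceForm.L_ONLY: ("CL|L", "L|CR"),
    SpliceForm.CONTROL: ("GUSB",),
}


@dataclass(frozen=True)
class DiagnosticSet:
    """Validated diagnostic probes for the five countable species."""

    probes: dict[str, str]  # probe name -> sequence
    form_probes: dict[SpliceForm, tuple[str, ...]]
    flank: int

    def exclusive_probes(self, form: SpliceForm) -> frozenset[str]:
        """Probes used by some other form but not by ``form``."""
        own = set(self.form_probes[form])
        other = set()
        for g, names in self.form_probes.items():
            if g is not form:
                other.update(set(names) - own)
        return frozenset(other)


def build_diagnostics(design: AmpliconDesign, flank: int = 10) -> DiagnosticSet:
    """Construct junction probes and validate that they discriminate.

    Validation runs the classifier on the four error-free templates plus the
    control; the result must be the identity.  A non-discriminative set
    (two templates classifying identically, or any collision) raises
    :class:`DesignError` naming the offenders.
    """
    if flank < 4:
        raise DesignError("flank must be >= 4")
    probes: dict[str, str] = {}
    for name, (lrole, rrole) in _JUNCTIONS.items():
        left = design.segments[lrole].sequence
        right = design.segments[rrole].sequence
        if len(left) < flank or len(right) < flank:
            raise DesignError(
                f"segments {lrole.value}/{rrole.value} too short for flank {flank}"
            )
        probes[name] = left[-flank:] + right[:flank]
    if design.control_sequence:
        ctrl = design.control_sequence
        if len(ctrl) < 2 * flank:
            raise DesignError("control sequence too short for probe")
        mid = len(ctrl) // 2
        probes["GUSB"] = ctrl[mid - flank : mid + flank]
    for name, p in probes.items():
        if len(p) < 12:
            raise DesignError(f"diagnostic {name} shorter than 12 nt")

    form_probes = {
        f: names
        for f, names in _FORM_JUNCTIONS.items()
        if f is not SpliceForm.CONTROL or "GUSB" in probes
    }
    diag = DiagnosticSet(probes=probes, form_probes=form_probes, flank=flank)

    templates = build_templates(design)
    collisions = []
    for form in form_probes:
        call = classify_read(templates[form], diag, both_strands=False)
        if call is not form:
            collisions.append((str(form), str(call)))
    if collisions:
        raise DesignError(
            "diagnostic set is not discriminative on the design templates: "
            + ", ".join(f"template {t} classifies as {c}" for t, c in collisions)
        )
    return diag


def _probe_hits(
    seq: str, diagnostics: DiagnosticSet, max_error_rate: float
) -> set[str]:
    hits = set()
    for name, probe in diagnostics.probes.items():
        k = math.floor(max_error_rate * len(probe))
        if edlib.align(probe, seq, mode="HW", k=k)["editDistance"] != -1:
            hits.add(name)
    return hits


def _call_from_hits(hits: set[str], diagnostics: DiagnosticSet) -> SpliceForm:
    call = SpliceForm.UNASSIGNED
    for form, names in diagnostics.form_probes.items():
        if set(names) <= hits and not (diagnostics.exclusive_probes(form) & hits):
            if call is not SpliceForm.UNASSIGNED:
                return SpliceForm.UNASSIGNED  # ambiguous: two forms qualify
            call = form
    return call


def classify_read(
    seq: str | Read,
    diagnostics: DiagnosticSet,
    max_error_rate: float = 0.10,
    both_strands: bool = True,
) -> SpliceForm:
    """Assign one merged read to a splice form, control, or UNASSIGNED.

    The read is evaluated in the given orientation first; a valid call wins.
    With ``both_strands`` the reverse complement is consulted when the
    forward orientation yields no call.  All failure modes (no probe hit,
    probes of two forms hitting) map to UNASSIGNED.
    """
    if isinstance(seq, Read):
        seq = seq.seq
    if not seq:
        return SpliceForm.UNASSIGNED
    call = _call_from_hits(_probe_hits(seq, diagnostics, max_error_rate), diagnostics)
    if call is SpliceForm.UNASSIGNED and both_strands:
        call = _call_from_hits(
            _probe_hits(reverse_complement(seq), diagnostics, max_error_rate),
            diagnostics,
        )
    return call


def count_splice_forms(
    batches: dict[str, list[Read | str]],
    diagnostics: DiagnosticSet,
    max_error_rate: float = 0.10,
    both_strands: bool = True,
    design: AmpliconDesign | None = None,
) -> SpliceFormCountTable:
    """Tally splice-form calls per sample.

    ``batches`` maps sample ids to merged reads.  Per sample the counts over
    the five species plus UNASSIGNED sum to the number of input reads.
    Passing the ``design`` enables an exact-template fast path (reads equal
    to a template skip probe matching; the validated diagnostics guarantee
    the same call).
    """
    template_lookup: dict[str, SpliceForm] = {}
    if design is not None:
        for form, tpl in build_templates(design).items():
            if form in diagnostics.form_probes:
                template_lookup[tpl] = form
    counts: dict[str, dict[SpliceForm, int]] = {}
    for sample_id, reads in batches.items():
        tally = {sp: 0 for sp in (*ALL_SPECIES, SpliceForm.UNASSIGNED)}
        for r in reads:
            s = r.seq if isinstance(r, Read) else r
            call = template_lookup.get(s)
            if call is None:
                call = classify_read(s, diagnostics, max_error_rate, both_strands)
            tally[call] += 1
        counts[sample_id] = tally
    return SpliceFormCountTable.from_counts(counts)
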