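"""Synthetic data generators mirroring the measurement design.

Three generators cover the three data types the pipeline consumes:

* barcoded amplicon read pairs with PCR length bias and substitution
  sequencing error (:func:`simulate_readset`),
* equimolar spike-in mixture read sets for bias calibration
  (:func:`simulate_spikein_run`),
* droplet partitions for digital PCR (:func:`simulate_droplets`).

PCR bias is modelled as deterministic geometric amplification: a species
with per-cycle efficiency ``e`` is amplified by ``(1+e)**n_cycles``, and the
read-sampling probabilities are proportional to input molecules times that
factor.  The calibration stage estimates one factor per species regardless
of mechanism, so an expected-value model suffices.

Sequencing error is substitution-only by default (Illumina-like); an
optional indel rate exercises the fuzzy matchers.  All generators are
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALL_SPECIES,
    AmpliconDesign,
    Read,
    ReadPair,
    SpliceForm,
    build_templates,
    reverse_complement,
)

__all__ = [
    "PcrBiasSpec",
    "MixtureManifest",
    "DropletWell",
    "simulate_readset",
    "simulate_spikein_run",
    "simulate_droplets",
    "write_droplet_wells",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

#: Constant synthetic quality (phred 30) used unless an error profile is set.
DEFAULT_QUALITY_CHAR = chr(30 + 33)


@dataclass(frozen=True)
class PcrBiasSpec:
    """Per-species per-cycle amplification efficiencies.

    ``per_cycle_efficiency`` maps species to an efficiency in [0, 1]; each
    cycle multiplies that species' molecule count by ``1 + e`` (e = 0 is a
    legitimate reference baseline: no gain relative to the input).
    """

    per_cycle_efficiency: dict[SpliceForm, float]
    n_cycles: int = 32

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for sp, e in self.per_cycle_efficiency.items():
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"efficiency for {sp} must be in [0, 1], got {e}")

    def amplification_factor(self, species: SpliceForm) -> float:
        e = self.per_cycle_efficiency.get(SpliceForm(species))
        if e is None:
            raise KeyError(f"no efficiency for species {species}")
        return (1.0 + e) ** self.n_cycles


@dataclass(frozen=True)
class MixtureManifest:
    """One equimolar spike-in mixture: every species at the same molecule count."""

    mixture_id: str
    molecules_per_species: int
    species: tuple[SpliceForm, ...] = ALL_SPECIES

    def __post_init__(self) -> None:
        if self.molecules_per_species <= 0:
            raise ValueError("molecules_per_species must be > 0")


@dataclass(frozen=True)
class DropletWell:
    """Positive/negative droplet counts for one well and fluorescence channel."""

    well_id: str
    channel: str
    n_positive: int
    n_total: int
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError("n_positive must be in [0, n_total]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be > 0")

    @property
    def n_negative(self) -> int:
        return self.n_total - self.n_positive


def _apply_substitutions(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. substitution errors on a (n_reads, length) code matrix."""
    if rate <= 0 or codes.size == 0:
        return codes
    mask = rng.random(codes.shape) < rate
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        # shift by 1..3 mod 4 => always a different base
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return codes


def _rows_to_strings(codes: np.ndarray) -> list[str]:
    if codes.size == 0:
        return ["" for _ in range(codes.shape[0])]
    flat = _BASES[codes].tobytes().decode("ascii")
    w = codes.shape[1]
    return [flat[i * w : (i + 1) * w] for i in range(codes.shape[0])]


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Slow-path random single-base insertions/deletions (test knob)."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append("ACGT"[rng.integers(0, 4)])  # insertion
    return "".join(out)


def _effective_probs(
    templates: dict[SpliceForm, str],
    proportions: dict[SpliceForm, float],
    bias: PcrBiasSpec | None,
) -> tuple[list[SpliceForm], np.ndarray]:
    species = []
    weights = []
    for sp, p in proportions.items():
        sp = SpliceForm(sp)
        if sp not in templates:
            raise ValueError(f"proportion given for species {sp} absent from design")
        if p < 0:
            raise ValueError("proportions must be non-negative")
        w = p * (bias.amplification_factor(sp) if bias is not None else 1.0)
        species.append(sp)
        weights.append(w)
    total_p = sum(proportions.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total_p}")
    w = np.asarray(weights, dtype=float)
    return species, w / w.sum()


def simulate_readset(
    design: AmpliconDesign,
    proportions: dict[SpliceForm, float],
    n_read_pairs: int,
    seq_error_rate: float = 0.005,
    bias: PcrBiasSpec | None = None,
    read_length: int = 300,
    seed: int = 0,
    sample_index: int = 0,
    barcode_read: str = "r2",
    single_end: bool = False,
    indel_rate: float = 0.0,
    sample_id: str | None = None,
) -> list[ReadPair]:
    """Simulate one sample's barcoded amplicon read pairs.

    Each pair derives from one species template drawn with probability
    proportional to ``proportion * amplification factor``.  The forward read
    starts at the amplicon's 5' end; the mate reads back from the other end
    and begins with a fresh random quatromer followed by the sample's
    internal barcode (the reverse-primer tail architecture).  The barcode
    side is configurable via ``barcode_read`` ("r1" or "r2").  Substitution
    errors hit every emitted base i.i.d. at ``seq_error_rate``.

    Read ids carry the true species (``sim|<sample>|<index>|<species>``) for
    downstream truth-based evaluation; no pipeline stage reads them.
    """
    if n_read_pairs < 0:
        raise ValueError("n_read_pairs must be >= 0")
    if not (0.0 <= seq_error_rate < 0.5):
        raise ValueError("seq_error_rate must be in [0, 0.5)")
    if barcode_read not in ("r1", "r2"):
        raise ValueError("barcode_read must be 'r1' or 'r2'")
    templates = build_templates(design)
    species, probs = _effective_probs(templates, proportions, bias)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_read_pairs, probs)

    if sample_id is None:
        sample_id = f"S{sample_index:02d}"
    barcode = design.barcodes[sample_index]
    bc_codes = _ENCODE[np.frombuffer(barcode.encode(), dtype=np.uint8)]
    qlen = design.quatromer_length

    pairs: list[ReadPair] = []
    idx = 0
    for sp, m in zip(species, counts):
        if m == 0:
            continue
        amp = _ENCODE[np.frombuffer(templates[sp].encode(), dtype=np.uint8)]
        amp_rc = amp[::-1] ^ 3  # complement of ACGT codes is XOR 3

        # forward read: amplicon from its 5' end
        fwd_mol = np.tile(amp, (m, 1))
        # mate: quatromer + barcode + reverse-complemented amplicon
        quat = rng.integers(0, 4, size=(m, qlen), dtype=np.int64).astype(np.uint8)
        rev_mol = np.concatenate(
            [quat, np.tile(bc_codes, (m, 1)), np.tile(amp_rc, (m, 1))], axis=1
        )
        if barcode_read == "r1":
            fwd_mol, rev_mol = rev_mol, fwd_mol

        r1 = _apply_substitutions(fwd_mol[:, :read_length], seq_error_rate, rng)
        r2 = _apply_substitutions(rev_mol[:, :read_length], seq_error_rate, rng)
        seqs1 = _rows_to_strings(r1)
        seqs2 = _rows_to_strings(r2)
        if indel_rate > 0:
            seqs1 = [_apply_indels(s, indel_rate, rng) for s in seqs1]
            seqs2 = [_apply_indels(s, indel_rate, rng) for s in seqs2]
        for s1, s2 in zip(seqs1, seqs2):
            rid = f"sim|{sample_id}|{idx}|{sp}"
            q1 = DEFAULT_QUALITY_CHAR * len(s1)
            if single_end:
                # single-end layout reads from the barcode side so that
                # demultiplexing still sees the index
                pairs.append(ReadPair(Read(rid, s2, DEFAULT_QUALITY_CHAR * len(s2))))
            else:
                pairs.append(
                    ReadPair(
                        Read(rid, s1, q1),
                        Read(rid, s2, DEFAULT_QUALITY_CHAR * len(s2)),
                    )
                )
            idx += 1
    return pairs


def simulate_spikein_run(
    design: AmpliconDesign,
    manifests: list[MixtureManifest],
    bias: PcrBiasSpec | None,
    n_reads_per_mixture: int = 20000,
    seq_error_rate: float = 0.005,
    seed: int = 0,
    read_length: int = 300,
) -> tuple[dict[str, list[ReadPair]], pd.DataFrame]:
    """Simulate the equimolar spike-in mixtures as separate samples.

    Each mixture yields one read set whose expected species shares are
    proportional to ``molecules * (1+e)**n_cycles``; since mixtures are
    equimolar the molecule factor is common and bias alone shapes the
    shares.  Returns the per-mixture read sets and a manifest table
    (mixture_id, species, molecules).
    """
    if not manifests:
        raise ValueError("at least one mixture manifest is required")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(manifests))
    readsets: dict[str, list[ReadPair]] = {}
    rows = []
    for i, (manifest, child) in enumerate(zip(manifests, children)):
        props = {sp: 1.0 / len(manifest.species) for sp in manifest.species}
        readsets[manifest.mixture_id] = simulate_readset(
            design,
            props,
            n_reads_per_mixture,
            seq_error_rate=seq_error_rate,
            bias=bias,
            read_length=read_length,
            seed=int(child.generate_state(1)[0] % (2**31)),
            sample_index=i % design.n_samples,
            sample_id=manifest.mixture_id,
        )
        for sp in manifest.species:
            rows.append(
                {
                    "mixture_id": manifest.mixture_id,
                    "species": str(sp),
                    "molecules": manifest.molecules_per_species,
                }
            )
    return readsets, pd.DataFrame(rows)


def default_spikein_manifests() -> list[MixtureManifest]:
    """The six equimolar calibration mixtures.

    Template amounts follow a doubling series spanning a 16-fold range with
    the lowest amount replicated: 200 (twice), 400, 800, 1600 and 3200
    molecules per species.
    """
    amounts = [200, 200, 400, 800, 1600, 3200]
    return [
        MixtureManifest(mixture_id=f"MIX{i + 1}_{amt}", molecules_per_species=amt)
        for i, amt in enumerate(amounts)
    ]


def simulate_droplets(
    concentration_copies_per_ul: float,
    droplet_volume_nl: float = 0.85,
    n_droplets: int = 20000,
    seed: int = 0,
    well_id: str = "A01",
    channel: str = "FAM",
) -> DropletWell:
    """Partition a template solution into droplets.

    Each droplet receives a Poisson(lambda) molecule count with
    ``lambda = concentration [copies/uL] * droplet volume [uL]`` and is
    positive iff it holds at least one molecule.
    """
    if concentration_copies_per_ul < 0:
        raise ValueError("concentration must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be > 0")
    lam = concentration_copies_per_ul * droplet_volume_nl * 1e-3
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_droplets)
    return DropletWell(
        well_id=well_id,
        channel=channel,
        n_positive=int((counts > 0).sum()),
        n_total=n_droplets,
        droplet_volume_nl=droplet_volume_nl,
    )


def write_droplet_wells(path: str | Path, wells: list[DropletWell]) -> None:
    pd.DataFrame(
        [
            {
                "well_id": w.well_id,
                "channel": w.channel,
                "n_positive": w.n_positive,
                "n_total": w.n_total,
                "droplet_volume_nl": w.droplet_volume_nl,
            }
            for w in wells
        ]
    ).to_csv(path, sep="\t", index=False)
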