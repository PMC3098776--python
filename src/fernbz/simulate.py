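"""Synthetic BZ-like regions and gene orders with planted ground truth.

The generator emulates the feature statistics of the fern rpoB–psbZ
region so every detector in the package can be exercised against a
machine-readable truth without any sequence download:

* an i.i.d. nucleotide background at a configured GC content (plastome
  spacers are AT-rich; default GC 0.33);
* a tandem array of quasi-identical units — default geometry period 27,
  17 copies in modules of 5/6/6, the two later modules led by a
  distantly homologous "head" copy, and the unit derived from the
  anticodon domain of a planted trnY gene (459 bp of array inside a
  619 bp trnY–trnE spacer);
* dispersed hairpin elements with a fixed 7-nt A-rich loop (AAA adjacent
  to the stem) and configurable stem lengths;
* sigma70-style −35/−10 promoter box pairs on a chosen strand;
* optionally a full annotated gene region laid out from a named BZ gene
  order (Angiopteris/Plagiogyria/Adiantum types) scrambled by a chosen
  number of random interior inversions.

Everything placed is recorded in a :class:`PlantedTruth` object that
round-trips losslessly through JSON.  Identical seeds give identical
output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .gene_order import GeneOrder, InversionEvent, apply_inversion, load_catalog
from .seq_io import AnnotatedSequence, Feature, reverse_complement

__all__ = [
    "TandemSpec",
    "HairpinSpec",
    "PromoterSpec",
    "GeneOrderSpec",
    "SimConfig",
    "PlantedTruth",
    "simulate_region",
    "simulate_gene_orders",
    "equisetum_like_config",
    "vandenboschia_like_config",
    "EQUISETUM_STEM_HISTOGRAM",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Stem-length histogram of AAA-signature hairpins planted by the
#: E. ramosissimum-like profile (68 elements in a 5,000-nt spacer).
EQUISETUM_STEM_HISTOGRAM: dict[int, int] = {
    3: 21, 4: 3, 5: 8, 6: 8, 7: 2, 8: 16, 9: 6, 10: 2, 13: 2
}

# gene template lengths (nt) for the nine BZ loci, desk-realistic
_GENE_LENGTHS = {
    "B": 600,  # 3' portion of rpoB
    "C": 72,
    "N": 90,
    "M": 105,
    "D": 74,
    "Y": 84,
    "E": 73,
    "G": 72,
    "Z": 189,
}
_SYMBOL_TO_LOCUS = {
    "B": "rpoB",
    "C": "trnC-GCA",
    "N": "petN",
    "M": "psbM",
    "D": "trnD-GUC",
    "Y": "trnY-GUA",
    "E": "trnE-UUC",
    "G": "trnG-GCC",
    "Z": "psbZ",
}
_TRNA_SYMBOLS = set("CDYEG")

# trnY anticodon arm building blocks: GGA/TCC stem core, 7-nt loop with
# the GUA anticodon and the AAA signature adjacent to the 3' stem arm
_TRNY_ARM5 = "CAGGA"
_TRNY_LOOP = "TGTAAAA"
_TRNY_ARM3 = "TCCTG"
_TRNY_ARM_START = 19  # 1-based start of the 25-nt anticodon-arm window
_TRNY_ARM_END = 43


@dataclass(frozen=True)
class TandemSpec:
    period: int = 27
    copies: int = 17
    module_sizes: tuple[int, ...] = (5, 6, 6)
    per_copy_sub_rate: float = 0.02
    head_divergence: float = 0.30
    unit: str | None = None  # None: derive from trnY (gene mode) or random


@dataclass(frozen=True)
class HairpinSpec:
    """One hairpin element type: ``count`` identical dispersed copies.

    Copies share a single randomly drawn stem, emulating families of
    direct repeats that fold into one conserved stem-loop (stems conserved,
    loops fixed A-rich); elements of 2*stem_len + 7 >= 20 nt therefore
    also constitute detectable dispersed direct-repeat families.
    """

    stem_len: int
    count: int = 1
    loop_seq: str = "CTGTAAA"  # 7 nt, AAA adjacent to the 3' arm


@dataclass(frozen=True)
class PromoterSpec:
    strand: str = "+"
    spacer: int = 17
    upstream_of: str | None = None  # locus symbol; None: free placement


@dataclass(frozen=True)
class GeneOrderSpec:
    base: str = "Angiopteris"
    n_inversions: int = 0


@dataclass
class SimConfig:
    seed: int
    region_len: int = 5000
    gc: float = 0.33
    tandem: TandemSpec | None = None
    hairpins: tuple[HairpinSpec, ...] = ()
    promoters: tuple[PromoterSpec, ...] = ()
    gene_order: GeneOrderSpec | None = None
    ye_igs_len: int | None = None  # gene mode: target trnY-trnE spacer length
    seq_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc {self.gc} outside [0, 1]")
        if self.tandem is not None:
            t = self.tandem
            if sum(t.module_sizes) != t.copies:
                raise ValueError(
                    f"module sizes {t.module_sizes} do not sum to {t.copies} copies"
                )
            if not 0 <= t.per_copy_sub_rate <= 1 or not 0 <= t.head_divergence <= 1:
                raise ValueError("tandem rates must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Machine-readable record of everything the simulator planted."""

    seq_id: str
    region_len: int
    genes: list[dict] = field(default_factory=list)
    igs: dict[str, list[int]] = field(default_factory=dict)
    tandem: dict | None = None
    hairpins: list[dict] = field(default_factory=list)
    promoters: list[dict] = field(default_factory=list)
    gene_order: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# low-level builders


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    return _background(rng, length, gc).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    if n_subs == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def make_trny_gene(rng: np.random.Generator, gc: float = 0.5) -> str:
    """An 84-nt synthetic trnY-GUA-like gene with a real anticodon arm.

    Positions 19..43 (1-based) hold the 25-nt D-arm-stem + anticodon-arm
    window: 8 nt of D-arm context, then a 5-bp GGA/TCC-core stem, the
    7-nt loop TGTAAAA (GUA anticodon, AAA adjacent to the 3' arm) and the
    complementary arm.  The flanking bases are chosen not to pair, so the
    planted 5-bp stem is maximal.
    """
    length = _GENE_LENGTHS["Y"]
    chars = list(_rand_seq(rng, length, gc))
    arm = (
        _rand_seq(rng, 8, gc) + _TRNY_ARM5 + _TRNY_LOOP + _TRNY_ARM3
    )
    chars[_TRNY_ARM_START - 1 : _TRNY_ARM_END] = list(arm)
    _break_pairing(chars, _TRNY_ARM_START - 2 + 8, _TRNY_ARM_END, rng)
    return "".join(chars)


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _break_pairing(chars: list[str], left0: int, right0: int, rng) -> None:
    """Ensure chars[left0] does not Watson-Crick pair chars[right0]."""
    if left0 < 0 or right0 >= len(chars):
        return
    if _PAIR[chars[left0]] == chars[right0]:
        options = [b for b in "ACGT" if b != _PAIR[chars[left0]]]
        chars[right0] = options[rng.integers(len(options))]


def _build_tandem(
    rng: np.random.Generator, spec: TandemSpec, unit: str
) -> tuple[str, dict]:
    """The concatenated array string plus its truth record."""
    p = spec.period
    head_subs = round(spec.head_divergence * p)
    head = _mutate(rng, unit, head_subs)  # one head, reused (identical modules)
    copies: list[str] = []
    head_indices: list[int] = []
    for mod_idx, size in enumerate(spec.module_sizes):
        for k in range(size):
            if mod_idx > 0 and k == 0:
                head_indices.append(len(copies))
                copies.append(head)
            else:
                n_subs = int(rng.binomial(p, spec.per_copy_sub_rate))
                copies.append(_mutate(rng, unit, n_subs))
    truth = {
        "period": p,
        "copies": len(copies),
        "module_sizes": list(spec.module_sizes),
        "head_indices": head_indices,
        "unit": unit,
        "copy_seqs": copies,
    }
    return "".join(copies), truth


def _build_hairpin(rng: np.random.Generator, spec: HairpinSpec, gc: float) -> str:
    if len(spec.loop_seq) != 7:
        raise ValueError("hairpin loop must be 7 nt")
    arm5 = _rand_seq(rng, spec.stem_len, gc)
    return arm5 + spec.loop_seq + reverse_complement(arm5)


def _build_promoter(rng: np.random.Generator, spec: PromoterSpec, gc: float) -> str:
    block = "TTGACA" + _rand_seq(rng, spec.spacer, gc) + "TATAAT"
    return block if spec.strand == "+" else reverse_complement(block)


# ---------------------------------------------------------------------------
# placement


def _place_elements(
    rng: np.random.Generator,
    region_len: int,
    elements: list[tuple[str, str, dict]],
    margin: int = 2,
) -> list[tuple[int, str, str, dict]]:
    """Choose non-overlapping 0-based starts for (tag, seq, info) elements.

    Raises before any output if the packing is infeasible.  Placement is
    by seeded rejection sampling with a fixed attempt budget.
    """
    need = sum(len(seq) + 2 * margin for _, seq, _ in elements)
    if need > region_len:
        raise ValueError(
            f"planted features need {need} nt (with margins) but the region "
            f"is only {region_len} nt"
        )
    occupied: list[tuple[int, int]] = []
    placed = []
    for tag, seq, info in sorted(elements, key=lambda e: -len(e[1])):
        size = len(seq)
        for _ in range(5000):
            start = int(rng.integers(margin, region_len - size - margin + 1))
            lo, hi = start - margin, start + size + margin
            if all(hi <= a or lo >= b for a, b in occupied):
                occupied.append((lo, hi))
                placed.append((start, tag, seq, info))
                break
        else:
            raise ValueError(
                f"could not place a {size}-nt {tag} element in {region_len} nt "
                "after 5000 attempts; loosen the packing"
            )
    return sorted(placed)


def _fill_region(
    rng: np.random.Generator,
    region_len: int,
    gc: float,
    placed: list[tuple[int, str, str, dict]],
) -> list[str]:
    chars = list(_background(rng, region_len, gc).tobytes().decode())
    for start, tag, seq, info in placed:
        chars[start : start + len(seq)] = list(seq)
        if tag == "hairpin":
            # flanks must not pair, so the planted stem length is maximal
            _break_pairing(chars, start - 1, start + len(seq), rng)
    return chars


# ---------------------------------------------------------------------------
# public API


def simulate_gene_orders(
    base: GeneOrder, k: int, seed: int
) -> tuple[GeneOrder, list[InversionEvent]]:
    """Apply ``k`` random interior inversions to ``base`` (events recorded)."""
    if k > 4:
        raise ValueError("at most 4 inversions are supported")
    rng = np.random.default_rng(seed)
    order = base
    events = []
    n = len(base)
    for _ in range(k):
        i = int(rng.integers(2, n))  # 2..n-1
        j = int(rng.integers(i, n))
        ev = InversionEvent(i, j)
        order = apply_inversion(order, ev)
        events.append(ev)
    return order, events


def simulate_region(cfg: SimConfig) -> tuple[AnnotatedSequence, PlantedTruth]:
    """Generate a region (bare spacer or fully annotated BZ record) + truth."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.gene_order is None:
        return _simulate_bare(cfg, rng)
    return _simulate_gene_region(cfg, rng)


def _planted_elements(
    cfg: SimConfig, rng: np.random.Generator, unit_source: str | None
) -> list[tuple[str, str, dict]]:
    elements: list[tuple[str, str, dict]] = []
    if cfg.tandem is not None:
        unit = cfg.tandem.unit
        if unit is None:
            if unit_source is not None:
                window = unit_source[_TRNY_ARM_START - 1 : _TRNY_ARM_END]
                unit = window + "TT"
                unit = unit[: cfg.tandem.period].ljust(cfg.tandem.period, "T")
            else:
                unit = _rand_seq(rng, cfg.tandem.period, cfg.gc)
        array, truth = _build_tandem(rng, cfg.tandem, unit)
        elements.append(("tandem", array, truth))
    for spec in cfg.hairpins:
        seq = _build_hairpin(rng, spec, cfg.gc)  # one prototype per element type
        for _ in range(spec.count):
            elements.append(
                ("hairpin", seq, {"stem_len": spec.stem_len, "loop_seq": spec.loop_seq})
            )
    for spec in cfg.promoters:
        if spec.upstream_of is None:
            seq = _build_promoter(rng, spec, cfg.gc)
            elements.append(
                ("promoter", seq, {"strand": spec.strand, "spacer": spec.spacer})
            )
    return elements


def _truth_from_placed(
    truth: PlantedTruth, placed: list[tuple[int, str, str, dict]], offset: int = 0
) -> None:
    """Record placed elements in truth; ``offset`` shifts to record coords."""
    for start0, tag, seq, info in placed:
        start = offset + start0 + 1
        if tag == "tandem":
            truth.tandem = {
                "start": start,
                "end": start + len(seq) - 1,
                **info,
            }
        elif tag == "hairpin":
            stem = info["stem_len"]
            truth.hairpins.append(
                {
                    "start": start,
                    "stem_len": stem,
                    "loop_start": start + stem,
                    "loop_seq": info["loop_seq"],
                    "end": start + len(seq) - 1,
                }
            )
        elif tag == "promoter":
            if info["strand"] == "+":
                m35 = [start, start + 5]
                m10 = [start + 6 + info["spacer"], start + 11 + info["spacer"]]
            else:
                m10 = [start, start + 5]
                m35 = [start + 6 + info["spacer"], start + 11 + info["spacer"]]
            truth.promoters.append(
                {
                    "strand": info["strand"],
                    "minus35": m35,
                    "minus10": m10,
                    "spacer": info["spacer"],
                    "upstream_of": info.get("upstream_of"),
                }
            )


def _simulate_bare(cfg: SimConfig, rng) -> tuple[AnnotatedSequence, PlantedTruth]:
    if any(p.upstream_of is not None for p in cfg.promoters):
        raise ValueError(
            "promoters pinned upstream of a locus need a gene_order config"
        )
    elements = _planted_elements(cfg, rng, unit_source=None)
    placed = _place_elements(rng, cfg.region_len, elements)
    chars = _fill_region(rng, cfg.region_len, cfg.gc, placed)
    truth = PlantedTruth(seq_id=cfg.seq_id, region_len=cfg.region_len)
    _truth_from_placed(truth, placed)
    return AnnotatedSequence(cfg.seq_id, "".join(chars)), truth


def _simulate_gene_region(cfg: SimConfig, rng) -> tuple[AnnotatedSequence, PlantedTruth]:
    spec = cfg.gene_order
    catalog = load_catalog()
    if spec.base not in catalog:
        raise KeyError(f"unknown base order {spec.base!r}")
    order, events = simulate_gene_orders(catalog[spec.base], spec.n_inversions, cfg.seed)

    trny = make_trny_gene(rng)
    gene_seqs = {
        sym: (trny if sym == "Y" else _rand_seq(rng, _GENE_LENGTHS[sym], 0.45))
        for sym, _ in order.loci
    }

    # build the trnY-trnE spacer as its own planted sub-region
    elements = _planted_elements(cfg, rng, unit_source=trny)
    sub_len = cfg.ye_igs_len
    if sub_len is None:
        sub_len = sum(len(s) + 6 for _, s, _ in elements) + 120
    placed = _place_elements(rng, sub_len, elements)
    ye_igs_chars = _fill_region(rng, sub_len, cfg.gc, placed)

    symbols = [sym for sym, _ in order.loci]
    adjacent_ye = {"Y", "E"} <= set(symbols) and abs(
        symbols.index("Y") - symbols.index("E")
    ) == 1
    if elements and not adjacent_ye:
        raise ValueError(
            "planted spacer features require trnY and trnE to be adjacent "
            f"in the simulated order {order}"
        )

    # promoters pinned upstream of a gene go into the preceding spacer
    pinned = [p for p in cfg.promoters if p.upstream_of is not None]

    chars: list[str] = []
    features: list[Feature] = []
    truth = PlantedTruth(seq_id=cfg.seq_id, region_len=0)
    default_igs = 110
    for idx, (sym, sign) in enumerate(order.loci):
        gene = gene_seqs[sym]
        strand = "+" if sign > 0 else "-"
        start = len(chars) + 1
        chars.extend(gene if sign > 0 else reverse_complement(gene))
        features.append(
            Feature(
                locus=_SYMBOL_TO_LOCUS[sym],
                kind="tRNA" if sym in _TRNA_SYMBOLS else "gene",
                strand=strand,
                start=start,
                end=len(chars),
            )
        )
        if idx == len(order.loci) - 1:
            break
        next_sym, next_sign = order.loci[idx + 1]
        pair = {sym, next_sym}
        if pair == {"Y", "E"}:
            igs_start0 = len(chars)
            chars.extend(ye_igs_chars)
            _truth_from_placed(truth, placed, offset=igs_start0)
        else:
            igs = list(_rand_seq(rng, default_igs, cfg.gc))
            # plant pinned promoters upstream of the downstream-facing gene
            for p in pinned:
                target_sym = _symbol_of(p.upstream_of)
                block = "TTGACA" + _rand_seq(rng, p.spacer, cfg.gc) + "TATAAT"
                if target_sym == next_sym and next_sign > 0:
                    pos0 = len(igs) - len(block) - 8
                    igs[pos0 : pos0 + len(block)] = list(block)
                    _record_pinned(truth, len(chars) + pos0 + 1, p, "+")
                elif target_sym == sym and sign < 0:
                    rc = reverse_complement(block)
                    igs[8 : 8 + len(rc)] = list(rc)
                    _record_pinned(truth, len(chars) + 8 + 1, p, "-")
            chars.extend(igs)
    residues = "".join(chars)
    aseq = AnnotatedSequence(cfg.seq_id, residues, features)
    truth.region_len = len(residues)
    truth.genes = [
        {"locus": f.locus, "kind": f.kind, "strand": f.strand,
         "start": f.start, "end": f.end}
        for f in features
    ]
    for name, (a, b) in _igs_spans(features).items():
        truth.igs[name] = [a, b]
    truth.gene_order = {
        "base": spec.base,
        "events": [[ev.i, ev.j] for ev in events],
        "order": str(order),
    }
    return aseq, truth


def _record_pinned(truth: PlantedTruth, start: int, spec: PromoterSpec, strand: str):
    if strand == "+":
        m35 = [start, start + 5]
        m10 = [start + 6 + spec.spacer, start + 11 + spec.spacer]
    else:
        m10 = [start, start + 5]
        m35 = [start + 6 + spec.spacer, start + 11 + spec.spacer]
    truth.promoters.append(
        {
            "strand": strand,
            "minus35": m35,
            "minus10": m10,
            "spacer": spec.spacer,
            "upstream_of": spec.upstream_of,
        }
    )


def _symbol_of(locus: str) -> str:
    from .seq_io import locus_to_symbol

    return locus_to_symbol(locus)


def _igs_spans(features: list[Feature]) -> dict[str, tuple[int, int]]:
    spans = {}
    ordered = sorted(features, key=lambda f: f.start)
    for a, b in zip(ordered, ordered[1:]):
        name = f"{a.locus}--{b.locus}"
        spans[name] = (a.end + 1, b.start - 1)
    return spans


# ---------------------------------------------------------------------------
# study-condition profiles


def equisetum_like_config(seed: int, region_len: int = 5000) -> SimConfig:
    """A 5,000-nt spacer planted with the E. ramosissimum-like hairpin set:
    68 AAA-signature stem-loops with the reference stem-length histogram."""
    hairpins = tuple(
        HairpinSpec(stem_len=stem, count=count)
        for stem, count in sorted(EQUISETUM_STEM_HISTOGRAM.items())
    )
    return SimConfig(
        seed=seed, region_len=region_len, gc=0.33, hairpins=hairpins,
        seq_id=f"equisetum_like_seed{seed}",
    )


def vandenboschia_like_config(seed: int) -> SimConfig:
    """An annotated Angiopteris-order record whose trnY–trnE spacer holds
    the V. radicans-like 17 x 27 bp array (5/6/6 modules, 459 bp) inside a
    619-nt spacer, with a promoter pair upstream of the inverted trnD."""
    return SimConfig(
        seed=seed,
        gc=0.33,
        tandem=TandemSpec(),
        gene_order=GeneOrderSpec(base="Angiopteris", n_inversions=0),
        promoters=(PromoterSpec(strand="-", spacer=17, upstream_of="trnD-GUC"),),
        ye_igs_len=619,
        seq_id=f"vandenboschia_like_seed{seed}",
    )
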