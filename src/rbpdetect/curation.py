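"""Curation of annotated phage proteins from GenBank records.

Coding sequences are labelled *RBP* (receptor-binding protein: tail fibers,
tailspikes, receptor-binding/-recognizing proteins) or *Other* from their
``/product`` annotation, then filtered for misleading keywords, unknown
residues and implausible lengths, deduplicated, optionally subsampled on
the Other side, and split into train/test partitions by genome record date.
Every removal is tallied in a ledger so that input and output counts always
reconcile.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AA_INDEX

# RBP keyword pattern: tail fiber/fibre, tail spike, receptor-binding
# protein, receptor-recognizing protein, with optional space or hyphen
# between the words.  Bare "spike", "fiber" or "binding protein" never
# match: they are too ambiguous to label a protein an RBP.
RBP_PATTERN = re.compile(
    r"tail[ -]?fib(?:er|re)"
    r"|tail[ -]?spike"
    r"|receptor[ -]binding protein"
    r"|receptor[ -]recognizing protein",
    re.IGNORECASE,
)

# Annotation keywords that disqualify a regex-matched product: proteins
# related to RBPs (assembly chaperones, baseplate parts, ...) that are not
# receptor-binding proteins themselves.
RBP_EXCLUSIONS: tuple[str, ...] = (
    "adaptor", "wedge", "baseplate", "hinge", "connector", "structural",
    "component", "assembly", "chaperone", "attachment", "capsid",
    "proximal", "measure",
)

# Keywords that disqualify an Other product: unannotated or tentatively
# annotated proteins might be RBPs in disguise, so they are unsafe negatives.
OTHER_EXCLUSIONS: tuple[str, ...] = (
    "probable", "probably", "uncharacterized", "uncharacterised",
    "putative", "hypothetical", "unknown", "predicted",
)

RBP_MIN_LENGTH = 200
RBP_MAX_LENGTH = 1500
OTHER_MIN_LENGTH = 30


@dataclass
class CdsRecord:
    """One coding sequence: its protein translation and provenance."""

    genome_accession: str
    protein_id: str
    product: str
    sequence: str
    record_date: date

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CurationConfig:
    """Tunable knobs of the curation pipeline."""

    cutoff: tuple[int, int] = (2021, 9)  # train includes this year-month
    subsample_ratio: float | None = 10.0  # Others kept per retained RBP
    seed: int = 42

    def to_dict(self) -> dict:
        return {
            "cutoff": f"{self.cutoff[0]:04d}-{self.cutoff[1]:02d}",
            "subsample_ratio": self.subsample_ratio,
            "seed": self.seed,
        }


@dataclass
class CuratedDataset:
    """Filtered, deduplicated and partitioned RBP/Other protein sets."""

    rbps: list[CdsRecord]
    others: list[CdsRecord]
    split: dict[str, str]  # protein_id -> "train" | "test"
    ledger: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.rbps) + len(self.others) + sum(self.ledger.values())


def match_rbp_annotation(product: str) -> bool:
    """True iff the product annotation names an RBP keyword variant."""
    return bool(RBP_PATTERN.search(product))


def is_excluded_rbp(product: str) -> bool:
    """True iff an RBP-matched product carries a disqualifying keyword."""
    low = product.lower()
    return any(k in low for k in RBP_EXCLUSIONS)


def is_excluded_other(product: str) -> bool:
    """True iff an Other product is too uncertain to use as a negative."""
    low = product.lower()
    return any(k in low for k in OTHER_EXCLUSIONS)


def passes_quality_filters(record: CdsRecord, group: str) -> tuple[bool, str | None]:
    """Length and residue-quality check for one labelled record.

    Returns ``(True, None)`` or ``(False, reason)`` with reason
    ``"unknown_aa"`` or ``"length"``.  A single trailing stop ``*`` (an
    artifact of some GenBank translations) is ignored.
    """
    if group not in ("RBP", "Other"):
        raise ValueError(f"unknown group {group!r}")
    seq = record.sequence.rstrip("*") if record.sequence.endswith("*") else record.sequence
    if not seq or any(c not in AA_INDEX for c in seq.upper()):
        return False, "unknown_aa"
    n = len(seq)
    if group == "RBP" and not (RBP_MIN_LENGTH <= n <= RBP_MAX_LENGTH):
        return False, "length"
    if group == "Other" and n < OTHER_MIN_LENGTH:
        return False, "length"
    return True, None


def deduplicate(
    rbps: Sequence[CdsRecord], others: Sequence[CdsRecord]
) -> tuple[list[CdsRecord], list[CdsRecord], dict[str, int]]:
    """Collapse exact-sequence duplicates within groups; drop cross-group ones.

    Within each group the first occurrence (stable input order) is kept.  A
    sequence present in both groups is removed from both, since its label
    is ambiguous evidence.  Counts are returned per removal category.
    """
    counts = {"dup_within_rbp": 0, "dup_within_other": 0,
              "dup_cross_rbp": 0, "dup_cross_other": 0}

    def collapse(records: Sequence[CdsRecord], key: str) -> list[CdsRecord]:
        seen: set[str] = set()
        out = []
        for r in records:
            if r.sequence in seen:
                counts[key] += 1
            else:
                seen.add(r.sequence)
                out.append(r)
        return out

    rbps1 = collapse(rbps, "dup_within_rbp")
    others1 = collapse(others, "dup_within_other")
    rbp_seqs = {r.sequence for r in rbps1}
    other_seqs = {r.sequence for r in others1}
    shared = rbp_seqs & other_seqs
    rbps2 = [r for r in rbps1 if r.sequence not in shared]
    others2 = [r for r in others1 if r.sequence not in shared]
    counts["dup_cross_rbp"] = len(rbps1) - len(rbps2)
    counts["dup_cross_other"] = len(others1) - len(others2)
    return rbps2, others2, counts


def split_by_date(
    records: Iterable[CdsRecord], cutoff: tuple[int, int] = (2021, 9)
) -> dict[str, str]:
    """Assign ``train`` to records dated up to and including the cutoff month."""
    out: dict[str, str] = {}
    for r in records:
        d = r.record_date
        if not isinstance(d, date):
            raise ValueError(f"{r.protein_id}: unparseable record date {d!r}")
        out[r.protein_id] = "train" if (d.year, d.month) <= cutoff else "test"
    return out


def subsample_others(
    others: Sequence[CdsRecord], n_rbp: int, ratio: float, seed: int
) -> list[CdsRecord]:
    """Uniform random subset of Others of size ``round(ratio * n_rbp)``.

    Reproducible for a given seed; input order is preserved in the output.
    """
    size = int(round(ratio * n_rbp))
    if size > len(others):
        raise ValueError(
            f"requested {size} Others but only {len(others)} available"
        )
    if size == len(others):
        return list(others)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(others), size=size, replace=False)
    return [others[i] for i in sorted(idx)]


def parse_genbank(paths: Iterable[str | Path]) -> tuple[list[CdsRecord], int]:
    """Extract CDS proteins from GenBank flat files.

    CDS features without a ``/translation`` qualifier are translated from
    the genome with translation table 11; features that still yield no
    protein are skipped and counted.  Returns ``(records, n_skipped)``.
    """
    records: list[CdsRecord] = []
    skipped = 0
    for path in paths:
        path = Path(path)
        try:
            parsed = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:
            raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
        if not parsed:
            raise ValueError(f"GenBank file {path} contains no records")
        for rec in parsed:
            rec_date = _record_date(rec)
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                quals = feat.qualifiers
                product = quals.get("product", [""])[0]
                protein_id = quals.get("protein_id", [""])[0] or (
                    f"{rec.id}_{int(feat.location.start)}"
                )
                translation = quals.get("translation", [None])[0]
                if translation is None:
                    try:
                        translation = str(
                            feat.extract(rec.seq).translate(table=11, to_stop=True)
                        )
                    except Exception:
                        translation = ""
                translation = translation.rstrip("*")
                if not translation:
                    skipped += 1
                    continue
                records.append(
                    CdsRecord(
                        genome_accession=rec.id,
                        protein_id=protein_id,
                        product=product,
                        sequence=translation.upper(),
                        record_date=rec_date,
                    )
                )
    return records, skipped


def _record_date(rec) -> date:
    raw = rec.annotations.get("date")
    if not raw:
        raise ValueError(f"record {rec.id} has no date annotation")
    try:
        return datetime.strptime(raw, "%d-%b-%Y").date()
    except ValueError as exc:
        raise ValueError(f"record {rec.id}: unparseable date {raw!r}") from exc


def curate_records(
    records: Sequence[CdsRecord], config: CurationConfig | None = None
) -> CuratedDataset:
    """Run the full curation cascade on already-parsed CDS records.

    Order: keyword labelling, per-group exclusion keywords, quality filters
    (unknown residues, length), deduplication, Other subsampling, and the
    date-based train/test split.  The ledger counts removals per step and,
    together with the retained records, always accounts for every input.
    """
    config = config or CurationConfig()
    ledger: dict[str, int] = {}

    rbps: list[CdsRecord] = []
    others: list[CdsRecord] = []
    for r in records:
        if match_rbp_annotation(r.product):
            if is_excluded_rbp(r.product):
                ledger["rbp_excluded_keyword"] = ledger.get("rbp_excluded_keyword", 0) + 1
            else:
                rbps.append(r)
        else:
            if is_excluded_other(r.product):
                ledger["other_excluded_keyword"] = ledger.get("other_excluded_keyword", 0) + 1
            else:
                others.append(r)

    def quality(group: str, pool: list[CdsRecord]) -> list[CdsRecord]:
        kept = []
        tag = group.lower()
        for r in pool:
            ok, reason = passes_quality_filters(r, group)
            if ok:
                kept.append(r)
            else:
                key = f"{tag}_{reason}"
                ledger[key] = ledger.get(key, 0) + 1
        return kept

    rbps = quality("RBP", rbps)
    others = quality("Other", others)

    rbps, others, dup_counts = deduplicate(rbps, others)
    for k, v in dup_counts.items():
        if v:
            ledger[k] = v

    if config.subsample_ratio is not None:
        before = len(others)
        others = subsample_others(
            others, len(rbps), config.subsample_ratio, config.seed
        )
        discarded = before - len(others)
        if discarded:
            ledger["other_subsample_discarded"] = discarded

    split = split_by_date(rbps + others, config.cutoff)
    return CuratedDataset(rbps=rbps, others=others, split=split, ledger=ledger)


def curate_dataset(
    genbank_paths: Iterable[str | Path], config: CurationConfig | None = None
) -> CuratedDataset:
    """Parse GenBank files and curate their CDS proteins (see curate_records)."""
    records, skipped = parse_genbank(genbank_paths)
    dataset = curate_records(records, config)
    if skipped:
        dataset.ledger["cds_without_translation"] = skipped
    return dataset


def write_fasta(dataset: CuratedDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write rbps.faa / others.faa with ``accession|protein_id|label|split`` headers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = (out_dir / "rbps.faa", out_dir / "others.faa")
    for path, pool, label in zip(paths, (dataset.rbps, dataset.others), ("RBP", "Other")):
        with open(path, "w") as fh:
            for r in pool:
                part = dataset.split.get(r.protein_id, "train")
                fh.write(f">{r.genome_accession}|{r.protein_id}|{label}|{part}\n")
                for i in range(0, len(r.sequence), 60):
                    fh.write(r.sequence[i : i + 60] + "\n")
    return paths


def write_ledger(dataset: CuratedDataset, path: str | Path) -> None:
    """Write the removal ledger as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("step\tremoved\n")
        for k, v in dataset.ledger.items():
            fh.write(f"{k}\t{v}\n")
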