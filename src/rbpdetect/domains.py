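"""Domain-architecture calling and custom HMM construction for RBPs.

Phage receptor-binding proteins are modular: a structural N-terminal domain
that anchors the protein to the tail, and C-terminal domains that bind or
cleave the host receptor (or act as chaperones).  Residue 200 is used as
the cutoff between the two termini.  Proteins in which a known domain is
found at only one terminus are mined for new domain families: the unknown
terminus is excised, the excised parts are greedily clustered at high
identity, clusters with at least five members are aligned, and each
alignment yields a new profile HMM that augments the detection set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from Bio import Align

from .profile_hmm import (
    DEFAULT_BIT_THRESHOLD,
    DomainHit,
    Msa,
    ProfileHMM,
    build_from_msa,
    scan_sequence,
)

#: First-200-residue convention: a hit starting at or before this residue
#: belongs to the N-terminus.
N_TERMINUS_CUTOFF = 200

#: Greedy clustering identity threshold (fraction of the shorter sequence).
DEFAULT_CLUSTER_IDENTITY = 0.9

#: Minimum cluster size that justifies building a profile from it.
MIN_CLUSTER_SIZE = 5


def known_rbp_domain_names() -> dict[str, list[str]]:
    """Names of the curated Pfam domain families, per terminus.

    The actual Pfam profiles are external inputs; only the curated name
    list ships with the package.
    """
    raw = resources.files("rbpdetect.data").joinpath("pfam_rbp_domains.json")
    data = json.loads(raw.read_text())
    return {"n_terminal": data["n_terminal"], "c_terminal": data["c_terminal"]}


@dataclass
class Architecture:
    """Ordered N/C-terminal domain composition of one protein."""

    target_id: str
    n_terminal_domains: list[DomainHit]
    c_terminal_domains: list[DomainHit]

    @property
    def signature(self) -> tuple[str, ...]:
        ordered = sorted(
            self.n_terminal_domains + self.c_terminal_domains,
            key=lambda h: (h.ali_start, h.hmm_name),
        )
        return tuple(h.hmm_name for h in ordered)

    @property
    def n_hits(self) -> int:
        return len(self.n_terminal_domains) + len(self.c_terminal_domains)


@dataclass
class TerminusPart:
    """An excised terminus of a one-sided protein (1-based inclusive)."""

    parent_id: str
    side: str  # "N" | "C"
    subsequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.side not in ("N", "C"):
            raise ValueError("side must be 'N' or 'C'")
        if len(self.subsequence) != self.end - self.start + 1:
            raise ValueError("coordinates do not match subsequence length")


@dataclass
class Cluster:
    """A greedy cluster of terminus parts around a representative."""

    representative: TerminusPart
    members: list[TerminusPart] = field(default_factory=list)
    identity_threshold: float = DEFAULT_CLUSTER_IDENTITY

    @property
    def size(self) -> int:
        return len(self.members)


def call_architecture(target_id: str, hits: Sequence[DomainHit]) -> Architecture:
    """Partition a protein's hits into N- and C-terminal domains.

    A hit whose alignment starts at residue 200 or earlier is N-terminal;
    one starting at 201 or later is C-terminal.
    """
    n_side = sorted(
        (h for h in hits if h.ali_start <= N_TERMINUS_CUTOFF),
        key=lambda h: (h.ali_start, h.hmm_name),
    )
    c_side = sorted(
        (h for h in hits if h.ali_start > N_TERMINUS_CUTOFF),
        key=lambda h: (h.ali_start, h.hmm_name),
    )
    return Architecture(target_id, n_side, c_side)


def is_rbp_by_domains(architecture: Architecture) -> bool:
    """Domain-based detection rule: any recognized domain designates an RBP."""
    return architecture.n_hits > 0


def find_one_sided(
    architectures: Sequence[Architecture],
) -> tuple[list[Architecture], list[Architecture]]:
    """Split architectures into those missing an N- or a C-terminal domain.

    ``missing_N``: a C-terminal domain was found but no N-terminal one;
    ``missing_C``: the mirror case.  Proteins with hits on both sides or
    none appear in neither list.
    """
    missing_n = [a for a in architectures
                 if a.c_terminal_domains and not a.n_terminal_domains]
    missing_c = [a for a in architectures
                 if a.n_terminal_domains and not a.c_terminal_domains]
    return missing_n, missing_c


def extract_parts(
    missing_n: Sequence[Architecture],
    missing_c: Sequence[Architecture],
    sequences: dict[str, str],
) -> tuple[list[TerminusPart], list[str]]:
    """Excise the unknown terminus of each one-sided protein.

    For a protein without an N-terminal domain the first
    ``min(200, len)`` residues are taken; for one without a C-terminal
    domain everything after the last N-terminal hit is taken.  Proteins
    whose last N-terminal hit runs to the end yield an empty C part and
    are skipped (their ids are returned for logging).
    """
    parts: list[TerminusPart] = []
    skipped: list[str] = []
    for arch in missing_n:
        seq = sequences[arch.target_id]
        end = min(N_TERMINUS_CUTOFF, len(seq))
        parts.append(TerminusPart(arch.target_id, "N", seq[:end], 1, end))
    for arch in missing_c:
        seq = sequences[arch.target_id]
        last_end = max(h.ali_end for h in arch.n_terminal_domains)
        start = last_end + 1
        if start > len(seq):
            skipped.append(arch.target_id)
            continue
        parts.append(
            TerminusPart(arch.target_id, "C", seq[last_end:], start, len(seq))
        )
    return parts, skipped


_identity_aligner = Align.PairwiseAligner()
_identity_aligner.mode = "global"
_identity_aligner.match_score = 1
_identity_aligner.mismatch_score = 0
_identity_aligner.open_gap_score = 0
_identity_aligner.extend_gap_score = 0


def pairwise_identity(a: str, b: str) -> float:
    """Global identity between two sequences.

    Identical residues under a maximal-matching global alignment (gaps
    free, so the count equals the longest common subsequence), normalised
    by the shorter sequence's length — the convention used by greedy
    clustering tools.
    """
    if not a or not b:
        return 0.0
    matches = _identity_aligner.score(a, b)
    return matches / min(len(a), len(b))


def greedy_cluster(
    parts: Sequence[TerminusPart],
    identity_threshold: float = DEFAULT_CLUSTER_IDENTITY,
) -> list[Cluster]:
    """Greedy incremental clustering of terminus parts.

    Parts are processed longest first (ties broken by id for determinism);
    each joins the first existing cluster whose representative it matches
    at or above the identity threshold, otherwise it founds a new cluster
    and becomes its representative.
    """
    ordered = sorted(parts, key=lambda p: (-len(p.subsequence), p.parent_id))
    clusters: list[Cluster] = []
    for part in ordered:
        for cluster in clusters:
            ident = pairwise_identity(
                part.subsequence, cluster.representative.subsequence
            )
            if ident >= identity_threshold:
                cluster.members.append(part)
                break
        else:
            clusters.append(
                Cluster(representative=part, members=[part],
                        identity_threshold=identity_threshold)
            )
    return clusters


_star_aligner = Align.PairwiseAligner()
_star_aligner.mode = "global"
_star_aligner.match_score = 1.0
_star_aligner.mismatch_score = -1.0
_star_aligner.open_gap_score = -2.0
_star_aligner.extend_gap_score = -0.5


def align_cluster(cluster: Cluster, min_size: int = MIN_CLUSTER_SIZE) -> Msa | None:
    """Center-star multiple alignment of a cluster around its representative.

    Every member is globally aligned to the representative; insertions
    relative to the representative are merged column-wise ("once a gap,
    always a gap").  Clusters smaller than ``min_size`` are skipped
    (returns ``None``) — too few observations to estimate a profile from.
    """
    if cluster.size < min_size:
        return None
    rep = cluster.representative.subsequence
    R = len(rep)
    pairs = []  # per member: (gapped_rep, gapped_member)
    for member in cluster.members:
        if member is cluster.representative:
            pairs.append((rep, rep))
            continue
        aln = _star_aligner.align(rep, member.subsequence)[0]
        pairs.append((str(aln[0]), str(aln[1])))

    # insertions relative to the representative, per gap slot 0..R
    def insertion_profile(gapped_rep: str) -> list[int]:
        ins = [0] * (R + 1)
        pos = 0
        run = 0
        for c in gapped_rep:
            if c == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[R] = max(ins[R], run)
        return ins

    profiles = [insertion_profile(gr) for gr, _ in pairs]
    master = [max(p[i] for p in profiles) for i in range(R + 1)]

    rows = []
    for (gapped_rep, gapped_mem), prof in zip(pairs, profiles):
        row = []
        pos = 0
        j = 0
        n_chars = len(gapped_rep)
        while pos <= R:
            # copy this member's insertion block, padded to the master width
            block = []
            while j < n_chars and gapped_rep[j] == "-":
                block.append(gapped_mem[j])
                j += 1
            block.extend("-" * (master[pos] - len(block)))
            row.extend(block)
            if pos < R:
                row.append(gapped_mem[j])
                j += 1
            pos += 1
        rows.append("".join(row))
    ids = [m.parent_id for m in cluster.members]
    return Msa(sequences=rows, ids=ids)


@dataclass
class CustomHmmReport:
    """Bookkeeping of one custom-HMM construction run."""

    n_scanned: int
    n_detected_before: int
    n_missing_n: int
    n_missing_c: int
    n_clusters: dict[str, int]
    n_built: dict[str, int]
    skipped_empty_parts: list[str]
    n_detected_after: int

    @property
    def additional_detections(self) -> int:
        return self.n_detected_after - self.n_detected_before

    def to_dict(self) -> dict:
        return {
            "n_scanned": self.n_scanned,
            "n_detected_before": self.n_detected_before,
            "n_missing_n": self.n_missing_n,
            "n_missing_c": self.n_missing_c,
            "n_clusters": self.n_clusters,
            "n_built": self.n_built,
            "skipped_empty_parts": self.skipped_empty_parts,
            "n_detected_after": self.n_detected_after,
            "additional_detections": self.additional_detections,
        }


def scan_proteins(
    sequences: dict[str, str],
    hmm_set: Sequence[ProfileHMM],
    threshold: float = DEFAULT_BIT_THRESHOLD,
) -> list[Architecture]:
    """Scan every protein and call its domain architecture."""
    return [
        call_architecture(pid, scan_sequence(seq, pid, list(hmm_set), threshold))
        for pid, seq in sequences.items()
    ]


def construct_custom_hmms(
    sequences: dict[str, str],
    base_hmm_set: Sequence[ProfileHMM],
    threshold: float = DEFAULT_BIT_THRESHOLD,
    identity_threshold: float = DEFAULT_CLUSTER_IDENTITY,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> tuple[list[ProfileHMM], CustomHmmReport]:
    """Build new HMMs from the unknown termini of one-sided proteins.

    Pipeline: scan with the base set, find one-sided architectures, excise
    the unknown terminus, cluster each side greedily, align clusters of at
    least ``min_cluster_size`` members and estimate a profile from each
    alignment.  Returns the augmented HMM set (base profiles first) and a
    report that includes the detection gain on ``sequences`` when
    re-scanned with the augmented set.
    """
    base = list(base_hmm_set)
    archs = scan_proteins(sequences, base, threshold)
    detected_before = sum(is_rbp_by_domains(a) for a in archs)
    missing_n, missing_c = find_one_sided(archs)
    parts, skipped = extract_parts(missing_n, missing_c, sequences)

    new_hmms: list[ProfileHMM] = []
    n_clusters: dict[str, int] = {}
    n_built: dict[str, int] = {}
    for side in ("N", "C"):
        side_parts = [p for p in parts if p.side == side]
        clusters = greedy_cluster(side_parts, identity_threshold)
        n_clusters[side] = len(clusters)
        built = 0
        for cluster in clusters:
            msa = align_cluster(cluster, min_cluster_size)
            if msa is None:
                continue
            built += 1
            new_hmms.append(
                build_from_msa(msa, name=f"custom_{side}_{built}")
            )
        n_built[side] = built

    augmented = base + new_hmms
    archs_after = scan_proteins(sequences, augmented, threshold)
    detected_after = sum(is_rbp_by_domains(a) for a in archs_after)

    report = CustomHmmReport(
        n_scanned=len(sequences),
        n_detected_before=detected_before,
        n_missing_n=len(missing_n),
        n_missing_c=len(missing_c),
        n_clusters=n_clusters,
        n_built=n_built,
        skipped_empty_parts=skipped,
        n_detected_after=detected_after,
    )
    return augmented, report


def architectures_to_rows(architectures: Sequence[Architecture]) -> list[dict]:
    """Flatten architectures for TSV export: one row per protein."""
    rows = []
    for a in architectures:
        hits = sorted(
            a.n_terminal_domains + a.c_terminal_domains,
            key=lambda h: (h.ali_start, h.hmm_name),
        )
        rows.append(
            {
                "target_id": a.target_id,
                "signature": ";".join(a.signature),
                "hits": ";".join(
                    f"{h.hmm_name}:{h.ali_start}-{h.ali_end}:{h.bit_score:.1f}"
                    for h in hits
                ),
                "is_rbp": int(is_rbp_by_domains(a)),
            }
        )
    return rows
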