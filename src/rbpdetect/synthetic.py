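"""Deterministic synthetic inputs for every stage of the pipeline.

Three generators produce the data the pipeline consumes in production,
with known ground truth:

* :func:`gen_genbank` — annotated phage-like GenBank records whose CDS
  products cover the RBP keyword space, the exclusion keywords and the
  quality-filter edge cases, with a per-CDS expected curation outcome;
* :func:`gen_modular_proteins` — modular RBP-like proteins built from
  reusable N- and C-terminal domain families, some withheld from the base
  HMM set to exercise custom-HMM construction;
* :func:`gen_two_class` — RBP/Other-style two-class protein sets with a
  controllable class separation, optionally with an HMM-score feature
  block carrying its own signal.

Every generator is a pure function of its spec (seed included): the same
spec yields byte-identical output.  Domain families follow a
conserved-plus-hypervariable model: each family fixes a consensus and a
set of variable positions (a fraction equal to the mutation rate), and
members differ from the consensus only at those positions — mimicking the
receptor-facing variability of real RBP domains while keeping every member
at least ``1 - rate`` identical to any other member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, BACKGROUND
from .profile_hmm import Msa, ProfileHMM, build_from_msa

# ---------------------------------------------------------------------------
# shared helpers

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A protein drawn iid from the background composition."""
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _back_translate(protein: str) -> str:
    return "".join(_CODON[c] for c in protein) + "TAA"


# ---------------------------------------------------------------------------
# GenBank fixture

#: Product strings that the RBP keyword pattern must accept.
RBP_PASS_PRODUCTS = (
    "tail fiber protein",
    "tail fibre protein",
    "tail-fiber protein",
    "tailspike protein",
    "tail spike protein",
    "tail-spike protein",
    "receptor-binding protein",
    "receptor binding protein",
    "receptor-recognizing protein",
)

#: Regex-matched products carrying a disqualifying keyword.
RBP_EXCLUDED_PRODUCTS = (
    "tail fiber assembly protein",
    "tail-fiber hinge connector",
    "tail spike baseplate protein",
    "tail fiber chaperone",
    "putative tail fiber assembly",
)

#: Safe negative annotations: no RBP keyword, no uncertainty keyword.
OTHER_PASS_PRODUCTS = (
    "major capsid protein",
    "portal protein",
    "terminase large subunit",
    "holin",
    "endolysin",
    "DNA polymerase",
    "tail protein",
    "spike protein",
    "binding protein",
    "integrase",
)

#: Negative annotations too uncertain to keep.
OTHER_EXCLUDED_PRODUCTS = (
    "hypothetical protein",
    "putative holin",
    "uncharacterized protein",
    "probable portal protein",
    "predicted terminase",
)


@dataclass
class GenBankFixtureSpec:
    """Composition of the annotated-genome fixture.

    ``category_counts`` maps outcome categories to CDS counts; ``*_pair``
    categories plant duplicate sequence pairs and count pairs, not CDSs.
    The default mix exercises every curation rule on 1,000 CDSs.
    """

    seed: int = 0
    n_genomes: int = 40
    train_fraction: float = 0.8
    cutoff: tuple[int, int] = (2021, 9)
    rbp_length: int = 300
    other_length: int = 120
    category_counts: dict[str, int] = field(
        default_factory=lambda: {
            "rbp_retained": 120,
            "rbp_excluded_keyword": 40,
            "rbp_too_short": 20,
            "rbp_too_long": 20,
            "rbp_unknown_aa": 20,
            "other_retained": 600,
            "other_excluded_keyword": 100,
            "other_too_short": 30,
            "other_unknown_aa": 20,
            "dup_within_rbp_pair": 5,
            "dup_within_other_pair": 5,
            "dup_cross_pair": 5,
        }
    )


def _plan_entries(spec: GenBankFixtureSpec, rng: np.random.Generator) -> list[dict]:
    """Plan (category, product, sequence, expected outcome) per CDS."""
    entries: list[dict] = []

    def add(category: str, product: str, seq: str,
            group: str, reason: str | None, pair: int | None = None) -> None:
        entries.append(
            {"category": category, "product": product, "sequence": seq,
             "expected_group": group, "removal_reason": reason or "",
             "pair": pair}
        )

    c = spec.category_counts
    for i in range(c.get("rbp_retained", 0)):
        add("rbp_retained", RBP_PASS_PRODUCTS[i % len(RBP_PASS_PRODUCTS)],
            random_protein(rng, spec.rbp_length), "rbp", None)
    for i in range(c.get("rbp_excluded_keyword", 0)):
        add("rbp_excluded_keyword",
            RBP_EXCLUDED_PRODUCTS[i % len(RBP_EXCLUDED_PRODUCTS)],
            random_protein(rng, spec.rbp_length), "removed", "rbp_excluded_keyword")
    for _ in range(c.get("rbp_too_short", 0)):
        add("rbp_too_short", "tail fiber protein",
            random_protein(rng, 150), "removed", "rbp_length")
    for _ in range(c.get("rbp_too_long", 0)):
        add("rbp_too_long", "tailspike protein",
            random_protein(rng, 1600), "removed", "rbp_length")
    for _ in range(c.get("rbp_unknown_aa", 0)):
        seq = random_protein(rng, spec.rbp_length)
        pos = int(rng.integers(1, len(seq) - 1))
        add("rbp_unknown_aa", "tail fiber protein",
            seq[:pos] + "X" + seq[pos + 1:], "removed", "rbp_unknown_aa")
    for i in range(c.get("other_retained", 0)):
        add("other_retained", OTHER_PASS_PRODUCTS[i % len(OTHER_PASS_PRODUCTS)],
            random_protein(rng, spec.other_length), "other", None)
    for i in range(c.get("other_excluded_keyword", 0)):
        add("other_excluded_keyword",
            OTHER_EXCLUDED_PRODUCTS[i % len(OTHER_EXCLUDED_PRODUCTS)],
            random_protein(rng, spec.other_length), "removed", "other_excluded_keyword")
    for _ in range(c.get("other_too_short", 0)):
        add("other_too_short", "holin", random_protein(rng, 20),
            "removed", "other_length")
    for _ in range(c.get("other_unknown_aa", 0)):
        seq = random_protein(rng, spec.other_length)
        pos = int(rng.integers(1, len(seq) - 1))
        add("other_unknown_aa", "portal protein",
            seq[:pos] + "X" + seq[pos + 1:], "removed", "other_unknown_aa")

    pair_id = 0
    for _ in range(c.get("dup_within_rbp_pair", 0)):
        seq = random_protein(rng, spec.rbp_length)
        add("dup_within_rbp_pair", "tail fiber protein", seq, "?", None, pair_id)
        add("dup_within_rbp_pair", "tailspike protein", seq, "?", None, pair_id)
        pair_id += 1
    for _ in range(c.get("dup_within_other_pair", 0)):
        seq = random_protein(rng, spec.other_length)
        add("dup_within_other_pair", "holin", seq, "?", None, pair_id)
        add("dup_within_other_pair", "endolysin", seq, "?", None, pair_id)
        pair_id += 1
    for _ in range(c.get("dup_cross_pair", 0)):
        seq = random_protein(rng, spec.rbp_length)
        add("dup_cross_pair", "tail fiber protein", seq,
            "removed", "dup_cross_rbp", pair_id)
        add("dup_cross_pair", "major capsid protein", seq,
            "removed", "dup_cross_other", pair_id)
        pair_id += 1

    rng.shuffle(entries)

    # resolve within-group duplicate pairs by final input order
    seen_pairs: set[int] = set()
    for e in entries:
        if e["expected_group"] != "?":
            continue
        grp = "rbp" if e["category"] == "dup_within_rbp_pair" else "other"
        if e["pair"] in seen_pairs:
            e["expected_group"] = "removed"
            e["removal_reason"] = f"dup_within_{grp}"
        else:
            seen_pairs.add(e["pair"])
            e["expected_group"] = grp
    return entries


def gen_genbank(
    spec: GenBankFixtureSpec, out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame]:
    """Write the annotated-genome fixture and its ground-truth table.

    Returns the GenBank file paths (one multi-record file) and a DataFrame
    with one row per CDS: expected curation group, removal reason (a ledger
    key, or empty) and train/test split.
    """
    rng = np.random.default_rng(spec.seed)
    entries = _plan_entries(spec, rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_genomes = spec.n_genomes
    n_test = int(round(n_genomes * (1.0 - spec.train_fraction)))
    per_genome = -(-len(entries) // n_genomes)  # ceil

    records = []
    truth_rows = []
    for g in range(n_genomes):
        chunk = entries[g * per_genome : (g + 1) * per_genome]
        if not chunk:
            break
        is_test = g >= n_genomes - n_test
        cy, cm = spec.cutoff
        if is_test:
            month, year = cm + 1 + (g % 3), cy
            date_str = f"15-{_MONTH[month]}-{year}"
            split = "test"
        else:
            month = 1 + (g % cm)
            year = cy
            date_str = f"15-{_MONTH[month]}-{year}"
            split = "train"
        accession = f"SYN{g:04d}"
        dna_parts, features = [], []
        offset = 0
        for j, e in enumerate(chunk):
            pid = f"{accession}_p{j:03d}"
            dna = _back_translate(e["sequence"])
            loc = FeatureLocation(offset, offset + len(dna), strand=1)
            features.append(
                SeqFeature(
                    loc,
                    type="CDS",
                    qualifiers={
                        "product": [e["product"]],
                        "protein_id": [pid],
                        "translation": [e["sequence"]],
                        "transl_table": ["11"],
                    },
                )
            )
            dna_parts.append(dna)
            offset += len(dna)
            truth_rows.append(
                {
                    "protein_id": pid,
                    "genome_accession": accession + ".1",
                    "category": e["category"],
                    "product": e["product"],
                    "length": len(e["sequence"]),
                    "expected_group": e["expected_group"],
                    "removal_reason": e["removal_reason"],
                    "split": split,
                }
            )
        rec = SeqRecord(
            Seq("".join(dna_parts)),
            id=accession + ".1",
            name=accession,
            description="synthetic phage genome",
            annotations={
                "molecule_type": "DNA",
                "date": date_str,
                "topology": "linear",
                "data_file_division": "PHG",
            },
        )
        rec.features = features
        records.append(rec)

    path = out_dir / "genomes.gbk"
    SeqIO.write(records, str(path), "genbank")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return [path], truth


_MONTH = {
    1: "JAN", 2: "FEB", 3: "MAR", 4: "APR", 5: "MAY", 6: "JUN",
    7: "JUL", 8: "AUG", 9: "SEP", 10: "OCT", 11: "NOV", 12: "DEC",
}


# ---------------------------------------------------------------------------
# modular-protein fixture


@dataclass
class DomainFamily:
    """A synthetic domain family: consensus plus hypervariable positions."""

    name: str
    side: str  # "N" | "C"
    consensus: str
    variable_positions: np.ndarray
    known: bool  # included in the base HMM set?

    def sample_member(self, rng: np.random.Generator) -> str:
        seq = list(self.consensus)
        for p in self.variable_positions:
            seq[p] = AMINO_ACIDS[int(rng.integers(20))]
        return "".join(seq)


@dataclass
class ModularFixtureSpec:
    """Composition of the modular-protein fixture.

    N-terminal domains span exactly the first 200 residues (the terminus
    convention's cutoff) so the C-terminal domain always starts after it.
    The mutation rate is the fraction of hypervariable positions per
    family.
    """

    seed: int = 0
    n_known_n: int = 2
    n_known_c: int = 2
    n_withheld_c: int = 3
    n_withheld_n: int = 0
    carriers_per_withheld: int = 6
    holdout_per_withheld: int = 10
    orphans_per_withheld: int = 3
    carriers_known: int = 10
    mutation_rate: float = 0.10
    n_len: int = 200
    c_len: int = 140
    linker_len: int = 0
    conserved_edge: int = 10  # domain boundaries are structurally constrained
    msa_members: int = 8


@dataclass
class ModularFixture:
    """Generated proteins, family truth and the base HMM set."""

    sequences: dict[str, str]  # pipeline input (training carriers)
    holdout: dict[str, str]  # carriers of withheld families, held out
    truth: pd.DataFrame
    families: list[DomainFamily]
    base_hmms: list[ProfileHMM]


def gen_modular_proteins(spec: ModularFixtureSpec) -> ModularFixture:
    """Generate modular RBP-like proteins with a partially known HMM set.

    Each protein is one N-family member followed by an optional background
    linker and one C-family member.  Families marked withheld do not enter
    the base HMM set, so their carriers present as one-sided architectures;
    each withheld family has enough training carriers to found one cluster
    that clears the minimum-size rule, plus held-out carriers for measuring
    recovery.
    """
    if spec.n_withheld_c > 0 and spec.n_known_n < 1:
        raise ValueError("withheld C families need at least one known N family")
    if spec.n_withheld_n > 0 and spec.n_known_c < 1:
        raise ValueError("withheld N families need at least one known C family")
    rng = np.random.default_rng(spec.seed)

    families: list[DomainFamily] = []

    def make_family(name: str, side: str, length: int, known: bool) -> DomainFamily:
        consensus = random_protein(rng, length)
        n_var = int(round(spec.mutation_rate * length))
        edge = spec.conserved_edge
        interior = np.arange(edge, length - edge)
        if n_var > interior.size:
            raise ValueError("mutation rate too high for the conserved edges")
        var = np.sort(rng.choice(interior, size=n_var, replace=False))
        fam = DomainFamily(name, side, consensus, var, known)
        families.append(fam)
        return fam

    known_n = [make_family(f"N_fam{i}", "N", spec.n_len, True)
               for i in range(spec.n_known_n)]
    known_c = [make_family(f"C_fam{i}", "C", spec.c_len, True)
               for i in range(spec.n_known_c)]
    withheld_c = [make_family(f"C_new{i}", "C", spec.c_len, False)
                  for i in range(spec.n_withheld_c)]
    withheld_n = [make_family(f"N_new{i}", "N", spec.n_len, False)
                  for i in range(spec.n_withheld_n)]

    sequences: dict[str, str] = {}
    holdout: dict[str, str] = {}
    rows = []

    def emit(pid: str, nf: DomainFamily, cf: DomainFamily, pool: dict) -> None:
        linker = random_protein(rng, spec.linker_len) if spec.linker_len else ""
        seq = nf.sample_member(rng) + linker + cf.sample_member(rng)
        pool[pid] = seq
        rows.append(
            {
                "protein_id": pid,
                "n_family": nf.name,
                "c_family": cf.name,
                "n_known": nf.known,
                "c_known": cf.known,
                "role": "holdout" if pool is holdout else "train",
                "c_start": spec.n_len + spec.linker_len + 1,
                "length": len(seq),
            }
        )

    for j in range(spec.carriers_known):
        emit(f"known_{j:03d}", known_n[j % len(known_n)],
             known_c[j % len(known_c)], sequences)
    for i, fam in enumerate(withheld_c):
        nf = known_n[i % len(known_n)]
        for j in range(spec.carriers_per_withheld):
            emit(f"{fam.name}_carrier_{j:03d}", nf, fam, sequences)
        for j in range(spec.holdout_per_withheld):
            emit(f"{fam.name}_holdout_{j:03d}", nf, fam, holdout)
        # orphans carry the withheld C family behind an unrelated N
        # terminus: undetectable with the base set, they are rescued only
        # once the custom C profile exists
        for j in range(spec.orphans_per_withheld):
            orphan_n = DomainFamily(
                f"random_N_{fam.name}_{j}", "N",
                random_protein(rng, spec.n_len),
                np.empty(0, dtype=int), False,
            )
            emit(f"{fam.name}_orphan_{j:03d}", orphan_n, fam, sequences)
    for i, fam in enumerate(withheld_n):
        cf = known_c[i % len(known_c)]
        for j in range(spec.carriers_per_withheld):
            emit(f"{fam.name}_carrier_{j:03d}", fam, cf, sequences)
        for j in range(spec.holdout_per_withheld):
            emit(f"{fam.name}_holdout_{j:03d}", fam, cf, holdout)

    base_hmms = [
        build_from_msa(
            Msa([fam.sample_member(rng) for _ in range(spec.msa_members)]),
            name=fam.name,
        )
        for fam in families
        if fam.known
    ]

    return ModularFixture(
        sequences=sequences,
        holdout=holdout,
        truth=pd.DataFrame(rows),
        families=families,
        base_hmms=base_hmms,
    )


def gen_decoys(
    sequences: dict[str, str], seed: int, n: int | None = None
) -> dict[str, str]:
    """Residue-shuffled decoys: same composition, destroyed domain order."""
    rng = np.random.default_rng(seed)
    items = list(sequences.items())
    if n is not None:
        reps = -(-n // len(items))
        items = (items * reps)[:n]
    out = {}
    for i, (pid, seq) in enumerate(items):
        chars = np.array(list(seq))
        rng.shuffle(chars)
        out[f"decoy_{i:03d}_{pid}"] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# two-class classifier fixture


@dataclass
class TwoClassSpec:
    """Composition of the RBP/Other-style classifier fixture.

    ``prevalence`` defaults to one positive per ten negatives, the class
    ratio the curation pipeline produces.  ``effect_size`` is the number
    of signature 3-mers implanted per positive sequence, at
    non-overlapping random positions (0 makes the classes exchangeable).
    ``hmm_effect`` adds a separate HMM-score feature block whose mean
    separates the classes by that many bits.
    """

    seed: int = 0
    n: int = 500
    length: int = 200
    prevalence: float = 1.0 / 11.0
    effect_size: float = 4.0
    signature: str = "WYW"
    hmm_effect: float = 0.0
    n_hmms: int = 5


@dataclass
class TwoClassData:
    ids: list[str]
    sequences: list[str]
    labels: np.ndarray
    hmm_scores: dict[str, np.ndarray] | None
    hmm_names: list[str]


def gen_two_class(spec: TwoClassSpec) -> TwoClassData:
    """Generate a labelled two-class protein set with tunable separability."""
    if spec.effect_size < 0:
        raise ValueError("effect size must be non-negative")
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n * spec.prevalence))
    labels = np.zeros(spec.n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    k = len(spec.signature)
    ids, seqs = [], []
    for i in range(spec.n):
        seq = list(random_protein(rng, spec.length))
        if labels[i] == 1 and spec.effect_size > 0:
            taken: list[int] = []
            n_implant = int(round(spec.effect_size))
            while len(taken) < n_implant:
                start = int(rng.integers(0, spec.length - k + 1))
                if all(abs(start - t) >= k for t in taken):
                    taken.append(start)
                    seq[start : start + k] = spec.signature
        ids.append(f"prot_{i:04d}")
        seqs.append("".join(seq))

    hmm_scores = None
    hmm_names = [f"hmm_{j}" for j in range(spec.n_hmms)]
    if spec.hmm_effect > 0:
        hmm_scores = {}
        for i, pid in enumerate(ids):
            loc = spec.hmm_effect if labels[i] == 1 else 0.0
            vec = rng.normal(loc, 1.0 + spec.hmm_effect / 10.0, size=spec.n_hmms)
            hmm_scores[pid] = np.clip(vec, 0.0, None)
    return TwoClassData(ids=ids, sequences=seqs, labels=labels,
                        hmm_scores=hmm_scores, hmm_names=hmm_names)
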