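"""Plain profile hidden Markov models for protein domain detection.

A :class:`ProfileHMM` is the classical match/insert/delete architecture:
``L`` match states with position-specific emission distributions, an insert
state after every node (plus one before the first match), and delete states
that skip match columns.  Profiles are built from multiple sequence
alignments with Laplace pseudocounts and scored against sequences by local
Viterbi log-odds in bits against a fixed background composition.

The scoring model is deliberately simple and fully specified so that it can
be verified against exhaustive path enumeration:

* an alignment enters the profile at any match state and leaves from any
  match state at no cost (flanking sequence is attributed to the background
  and cancels out of the log-odds);
* interior transitions use the profile's transition probabilities;
* match and insert emissions contribute ``log2(e(x) / bg(x))``; delete
  states emit nothing.

The best-scoring local alignment, its bit score and its 1-based inclusive
coordinates on the target are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, BACKGROUND, encode

# Transition slot order per node, matching the HMMER3 file layout:
# M->M, M->I, M->D, I->M, I->I, D->M, D->D.
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

#: Default bit-score threshold above which a domain hit is reported.
DEFAULT_BIT_THRESHOLD = 25.0


@dataclass
class Msa:
    """A multiple sequence alignment with ``-`` as the gap character."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("Msa requires at least one row")
        width = len(self.sequences[0])
        if any(len(s) != width for s in self.sequences):
            raise ValueError("Msa rows must all have the same length")
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0])


@dataclass
class ProfileHMM:
    """Profile HMM parameters in probability space.

    ``transitions`` has ``L + 1`` rows; row ``k`` holds the probabilities of
    leaving node ``k`` (row 0 is the begin node, row ``L`` leads to the end
    state).  Structural zeros (no delete state beyond the last match column)
    are kept as exact zeros.
    """

    name: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L + 1, 20)
    transitions: np.ndarray  # (L + 1, 7)
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.L < 1:
            raise ValueError("profile needs at least one match state")
        if self.insert_emissions.shape != (self.L + 1, 20):
            raise ValueError("insert_emissions must have L + 1 rows of 20")
        if self.transitions.shape != (self.L + 1, 7):
            raise ValueError("transitions must have L + 1 rows of 7")
        self.validate()

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, atol: float = 1e-4) -> None:
        """Check that all probability rows are normalised and non-negative.

        The default tolerance accommodates profiles read from HMMER3 text
        files, where probabilities are quantised to five decimals of their
        negative natural log; freshly built profiles are normalised to
        machine precision.
        """
        for name, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
            ("transitions", self.transitions),
        ):
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative probabilities")
        for label, rows in (
            ("match", self.match_emissions),
            ("insert", self.insert_emissions),
        ):
            dev = np.abs(rows.sum(axis=1) - 1.0)
            if dev.max() > atol:
                raise ValueError(f"{label} emission rows do not sum to 1")
        # transition triples normalise per source state
        t = self.transitions
        for sl, label in (
            (slice(T_MM, T_MD + 1), "M"),
            (slice(T_IM, T_II + 1), "I"),
            (slice(T_DM, T_DD + 1), "D"),
        ):
            dev = np.abs(t[:, sl].sum(axis=1) - 1.0)
            if dev.max() > atol:
                raise ValueError(f"{label}-state transition rows do not sum to 1")

    # cached log-odds tables, invalidated on demand only (profiles are
    # treated as immutable after construction)
    def _log_odds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not hasattr(self, "_lo_cache"):
            with np.errstate(divide="ignore"):
                lm = np.log2(self.match_emissions) - np.log2(self.background)
                li = np.log2(self.insert_emissions) - np.log2(self.background)
                lt = np.log2(self.transitions)
            self._lo_cache = (lm, li, lt)
        return self._lo_cache


@dataclass(frozen=True)
class DomainHit:
    """A scored profile-HMM match on a target protein (1-based inclusive)."""

    hmm_name: str
    target_id: str
    ali_start: int
    ali_end: int
    bit_score: float

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError("hit coordinates must satisfy 1 <= start <= end")


def build_from_msa(
    msa: Msa,
    name: str = "profile",
    gap_fraction_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns whose gap fraction is at most ``gap_fraction_threshold`` become
    match states.  Emission and transition probabilities are maximum
    likelihood over observed counts with a flat ``pseudocount`` added
    (Laplace smoothing); sequences are weighted uniformly.  Insert emissions
    are set to the background composition, so insertions are scored as
    neutral.
    """
    rows = [s.upper() for s in msa.sequences]
    ncol = msa.width
    nrow = msa.n_rows

    gap_frac = np.array(
        [sum(r[j] == "-" for r in rows) / nrow for j in range(ncol)]
    )
    is_match = gap_frac <= gap_fraction_threshold
    L = int(is_match.sum())
    if L == 0:
        raise ValueError("alignment has no match columns at this gap threshold")

    match_counts = np.zeros((L, 20))
    trans_counts = np.zeros((L + 1, 7))

    match_index = np.full(ncol, -1, dtype=int)
    match_index[is_match] = np.arange(L)

    for r in rows:
        # walk the state path of this sequence: M/D at match columns,
        # I between them; begin node is 0, end follows node L
        prev_state, prev_node = "M", 0  # begin treated as M0
        for j in range(ncol):
            c = r[j]
            if is_match[j]:
                k = match_index[j] + 1
                if c == "-":
                    state = "D"
                else:
                    state = "M"
                    match_counts[k - 1, AMINO_ACIDS.index(c)] += 1
                trans_counts[prev_node, _slot(prev_state, state)] += 1
                prev_state, prev_node = state, k
            elif c != "-":
                if prev_state == "D":
                    # delete->insert has no slot in the 7-transition plan;
                    # fold it through the preceding match (rare, and absent
                    # from ungapped fixtures)
                    prev_state = "M"
                if prev_state != "I":
                    trans_counts[prev_node, _slot(prev_state, "I")] += 1
                else:
                    trans_counts[prev_node, T_II] += 1
                prev_state = "I"
        trans_counts[prev_node, _slot(prev_state, "M")] += 1  # exit to end

    match_emissions = match_counts + pseudocount
    match_emissions /= match_emissions.sum(axis=1, keepdims=True)

    insert_emissions = np.tile(BACKGROUND, (L + 1, 1))

    transitions = _normalise_transitions(trans_counts, pseudocount, L)

    return ProfileHMM(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
    )


def _slot(src: str, dst: str) -> int:
    return {
        ("M", "M"): T_MM, ("M", "I"): T_MI, ("M", "D"): T_MD,
        ("I", "M"): T_IM, ("I", "I"): T_II,
        ("D", "M"): T_DM, ("D", "D"): T_DD,
    }[(src, dst)]


def _normalise_transitions(
    counts: np.ndarray, pseudocount: float, L: int
) -> np.ndarray:
    t = counts + pseudocount
    # structural zeros: no D0, no D_{L+1}
    t[0, T_DM], t[0, T_DD] = 1.0, 0.0
    t[L, T_MD] = 0.0
    t[L, T_DM], t[L, T_DD] = 1.0, 0.0
    out = np.zeros_like(t)
    for sl in (slice(T_MM, T_MD + 1), slice(T_IM, T_II + 1), slice(T_DM, T_DD + 1)):
        block = t[:, sl]
        out[:, sl] = block / block.sum(axis=1, keepdims=True)
    return out


def viterbi_score(hmm: ProfileHMM, seq: str) -> tuple[float, int, int]:
    """Best local-alignment log-odds of ``seq`` against ``hmm`` in bits.

    Returns ``(bit_score, ali_start, ali_end)`` with 1-based inclusive
    coordinates of the maximising alignment on the target.  Deterministic;
    ties resolve to the smallest end coordinate, then the smallest profile
    exit node.
    """
    if not seq:
        raise ValueError("cannot score an empty sequence")
    x = encode(seq.upper())
    n = len(x)
    L = hmm.L
    lm, li, lt = hmm._log_odds()

    NEG = -np.inf
    # vm[k-1] = best score of a path ending in match state k at the current
    # residue; vi likewise for insert state k; vd[k] holds delete-state
    # scores fed by the previous residue (deletes consume no residue, so
    # deletes computed after residue i feed matches at residue i + 1).
    vm = np.full(L, NEG)
    vi = np.full(L, NEG)
    vd = np.full(L + 1, NEG)
    # residue index (0-based) where each candidate alignment started
    sm = np.zeros(L, dtype=np.int64)
    si = np.zeros(L, dtype=np.int64)
    sd = np.zeros(L + 1, dtype=np.int64)

    em = lm[:, x]  # (L, n) match log-odds per position
    ei = li[1:, x]  # (L, n) insert log-odds, nodes 1..L
    t_mm, t_im, t_dm = lt[1:L, T_MM], lt[1:L, T_IM], lt[1:L, T_DM]
    t_mi, t_ii = lt[1:, T_MI], lt[1:, T_II]
    t_md = lt[1:L, T_MD]  # M_{k-1} -> D_k for k = 2..L
    cum_dd = np.concatenate(([0.0], np.cumsum(lt[2:L, T_DD])))  # chains D_2..D_k
    arangeL = np.arange(L)

    best = NEG
    best_end = best_k = best_start = -1

    for i in range(n):
        # match states: free local entry (score 0) or extension
        cand = np.empty((4, L))
        cand[0] = 0.0
        cand[1, 0] = cand[2, 0] = cand[3, 0] = NEG
        cand[1, 1:] = vm[:-1] + t_mm
        cand[2, 1:] = vi[:-1] + t_im
        cand[3, 1:] = vd[1:L] + t_dm
        choice = cand.argmax(axis=0)
        starts = np.empty((4, L), dtype=np.int64)
        starts[0] = i
        starts[1, 1:] = sm[:-1]
        starts[2, 1:] = si[:-1]
        starts[3, 1:] = sd[1:L]
        vm_new = cand[choice, arangeL] + em[:, i]
        sm_new = starts[choice, arangeL]

        # insert states at residue i (I_0 is unreachable: local alignments
        # must begin at a match state)
        from_m = vm + t_mi
        from_i = vi + t_ii
        use_m = from_m >= from_i
        vi = np.where(use_m, from_m, from_i) + ei[:, i]
        si = np.where(use_m, sm, si)

        # delete states fed by residue i: vd[k] = max(base[j] + sum of
        # D->D terms from j+1 to k) for j <= k, a running maximum after
        # subtracting the cumulative D->D chain
        if L > 1:
            base = vm_new[:-1] + t_md  # entry M_{k-1} -> D_k, k = 2..L
            g = base - cum_dd
            run = np.maximum.accumulate(g)
            origin = np.maximum.accumulate(
                np.where(g >= run, np.arange(L - 1), -1)
            )
            vd[2:] = run + cum_dd
            sd[2:] = sm_new[origin]

        vm, sm = vm_new, sm_new

        k_arg = int(vm.argmax())
        if vm[k_arg] > best:
            best, best_end, best_k = float(vm[k_arg]), i, k_arg
            best_start = int(sm[k_arg])

    if best_end < 0 or not np.isfinite(best):
        # every single-residue alignment has a finite score, so this cannot
        # happen for canonical input
        raise RuntimeError("Viterbi failed to produce a finite score")
    return best, best_start + 1, best_end + 1


def scan_sequence(
    seq: str,
    target_id: str,
    hmm_set: list[ProfileHMM],
    threshold: float = DEFAULT_BIT_THRESHOLD,
) -> list[DomainHit]:
    """Score ``seq`` against every profile; keep the best hit per profile.

    Hits with bit score below ``threshold`` are dropped.  The result is
    sorted by alignment start (ties by profile name) so that the N-to-C
    domain order is preserved.
    """
    if not hmm_set:
        raise ValueError("scan requires a non-empty HMM set")
    hits: list[DomainHit] = []
    for hmm in hmm_set:
        score, start, end = viterbi_score(hmm, seq)
        if score >= threshold:
            hits.append(DomainHit(hmm.name, target_id, start, end, score))
    hits.sort(key=lambda h: (h.ali_start, h.hmm_name))
    return hits
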