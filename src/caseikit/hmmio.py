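"""Profile HMMs: HMMER3 ASCII read/write, model construction and Viterbi scan.

The parser covers the subset of the HMMER3 ASCII profile format needed for
protein-family screening: NAME/ACC/LENG/ALPH headers, optional STATS lines,
and per-node match emissions, insert emissions and the seven core transitions
(values stored as negative natural logs, ``*`` meaning probability zero).

Scanning uses a uni-hit local Viterbi: any substring of the protein may align
to any sub-path of match states.  Local entry/exit probabilities are uniform
(1/M into each match state and 1/M out; a single-state model pays no entry or
exit cost), flanking residues are emitted by the background and contribute
zero to the log-odds score, and insert emissions come from the model.  Scores
are reported in bits.  E-values use the model's Gumbel calibration when the
file carries STATS lines, otherwise a documented default (lambda = 0.69,
tau = log2 of the model length times 400).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AMINO = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO)}

# Robinson & Robinson style background frequencies, order as AMINO
BACKGROUND = np.array(
    [
        0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
        0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
        0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0540978,
        0.0683364, 0.0540687, 0.0673417, 0.0114135, 0.0304133,
    ]
)

TRANSITION_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class HmmFormatError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """A protein profile HMM with M match states.

    Emission/transition arrays hold probabilities (not logs).  Transitions are
    indexed by source node 0..M, node 0 being the begin state; entry/exit for
    local alignment are configured at scan time, not taken from node 0.
    """

    name: str
    accession: str | None
    length: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M+1, 20)
    transitions: np.ndarray  # (M+1, 7) in TRANSITION_ORDER
    stats_viterbi: tuple[float, float] | None = None  # (mu, lambda)

    def __post_init__(self) -> None:
        assert self.length >= 1
        assert self.match_emissions.shape == (self.length, 20)
        sums = self.match_emissions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-3), "match emissions not normalized"


def _values(tokens: list[str]) -> list[float]:
    return [math.inf if t == "*" else float(t) for t in tokens]


def read_hmm(path: str | Path) -> list[ProfileHMM]:
    """Parse all models from a HMMER3 ASCII profile file."""
    models: list[ProfileHMM] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("HMMER3"):
            raise HmmFormatError(f"line {i + 1}: expected HMMER3 header, got {line[:40]!r}")
        name = acc = None
        length = None
        stats_vit = None
        i += 1
        while i < n and not lines[i].startswith("HMM "):
            key = lines[i][:5].strip()
            rest = lines[i][5:].strip()
            if key == "NAME":
                name = rest
            elif key == "ACC":
                acc = rest
            elif key == "LENG":
                length = int(rest)
            elif key == "ALPH" and rest.lower() != "amino":
                raise HmmFormatError(f"line {i + 1}: unsupported alphabet {rest!r}")
            elif key == "STATS":
                parts = rest.split()
                if len(parts) == 4 and parts[1] == "VITERBI":
                    stats_vit = (float(parts[2]), float(parts[3]))
            i += 1
        if i >= n or length is None or name is None:
            raise HmmFormatError(f"line {i + 1}: truncated model header")
        i += 2  # skip "HMM ..." emission header and transition header lines
        if i < n and lines[i].strip().startswith("COMPO"):
            i += 1
        # node 0: insert emissions + transitions
        try:
            ins0 = _values(lines[i].split())
            tr0 = _values(lines[i + 1].split())
            i += 2
        except (IndexError, ValueError) as exc:
            raise HmmFormatError(f"line {i + 1}: bad node-0 lines ({exc})")
        match_em = np.zeros((length, 20))
        ins_em = np.zeros((length + 1, 20))
        trans = np.zeros((length + 1, 7))
        ins_em[0] = np.exp(-np.array(ins0[:20]))
        trans[0] = np.exp(-np.array(tr0[:7]))
        for k in range(1, length + 1):
            try:
                mtok = lines[i].split()
                if int(mtok[0]) != k:
                    raise ValueError(f"expected node {k}, found {mtok[0]!r}")
                match_em[k - 1] = np.exp(-np.array(_values(mtok[1:21])))
                ins_em[k] = np.exp(-np.array(_values(lines[i + 1].split()[:20])))
                trans[k] = np.exp(-np.array(_values(lines[i + 2].split()[:7])))
                i += 3
            except (IndexError, ValueError) as exc:
                raise HmmFormatError(f"line {i + 1}: bad node {k} ({exc})")
        if i >= n or lines[i].strip() != "//":
            raise HmmFormatError(f"line {i + 1}: missing '//' terminator")
        i += 1
        models.append(
            ProfileHMM(
                name=name,
                accession=acc,
                length=length,
                match_emissions=match_em,
                insert_emissions=ins_em,
                transitions=trans,
                stats_viterbi=stats_vit,
            )
        )
    if not models:
        raise HmmFormatError("no models in file")
    return models


def _fmt(p: float) -> str:
    if p <= 0:
        return "*"
    return f"{-math.log(p):.5f}"


def write_hmm(models: list[ProfileHMM] | ProfileHMM, path: str | Path) -> None:
    if isinstance(models, ProfileHMM):
        models = [models]
    with open(path, "w") as fh:
        for m in models:
            fh.write("HMMER3/f [caseikit profile subset]\n")
            fh.write(f"NAME  {m.name}\n")
            if m.accession:
                fh.write(f"ACC   {m.accession}\n")
            fh.write(f"LENG  {m.length}\n")
            fh.write("ALPH  amino\n")
            if m.stats_viterbi:
                fh.write(f"STATS LOCAL VITERBI {m.stats_viterbi[0]:.4f} {m.stats_viterbi[1]:.5f}\n")
            fh.write("HMM  " + "  ".join(f"{a:>7}" for a in AMINO) + "\n")
            fh.write("     " + "  ".join(f"{t:>7}" for t in
                                         ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")) + "\n")
            fh.write("      " + " ".join(f"{_fmt(p):>8}" for p in m.insert_emissions[0]) + "\n")
            fh.write("      " + " ".join(f"{_fmt(p):>8}" for p in m.transitions[0]) + "\n")
            for k in range(1, m.length + 1):
                fh.write(f"{k:>7} " + " ".join(f"{_fmt(p):>8}" for p in m.match_emissions[k - 1]) + "\n")
                fh.write("        " + " ".join(f"{_fmt(p):>8}" for p in m.insert_emissions[k]) + "\n")
                fh.write("        " + " ".join(f"{_fmt(p):>8}" for p in m.transitions[k]) + "\n")
            fh.write("//\n")


def profile_from_sequences(
    seqs: list[str],
    name: str,
    accession: str | None = None,
    pseudocount: float = 0.3,
) -> ProfileHMM:
    """Build a simple ungapped profile HMM from one or more equal-length
    proteins (match state per column, pseudocounted emissions, high
    self-transition probabilities).  Used to construct synthetic family
    profiles for screening without external model downloads."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length")
    (M,) = lengths
    match_em = np.full((M, 20), pseudocount / 20.0)
    for s in seqs:
        for k, a in enumerate(s):
            if a in _AA_INDEX:
                match_em[k, _AA_INDEX[a]] += 1.0 / len(seqs)
    match_em /= match_em.sum(axis=1, keepdims=True)
    ins_em = np.tile(BACKGROUND, (M + 1, 1))
    trans = np.zeros((M + 1, 7))
    trans[:, 0] = 0.95  # m->m
    trans[:, 1] = 0.03  # m->i
    trans[:, 2] = 0.02  # m->d
    trans[:, 3] = 0.50  # i->m
    trans[:, 4] = 0.50  # i->i
    trans[:, 5] = 0.70  # d->m
    trans[:, 6] = 0.30  # d->d
    return ProfileHMM(
        name=name,
        accession=accession,
        length=M,
        match_emissions=match_em,
        insert_emissions=ins_em,
        transitions=trans,
    )


def encode_protein(seq: str) -> np.ndarray:
    """Residue indices into AMINO; unknown residues (X, B, Z, ...) get -1."""
    return np.array([_AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)


LOG0 = -1e30


def hmm_scan(
    protein: str, hmm: ProfileHMM, n_targets: int = 1, gumbel_lambda: float = 0.69
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Uni-hit local Viterbi scan of one protein against one profile.

    Returns (bit_score, e_value, span) where span is (protein start, protein
    end, first match state, last match state), all 1-based inclusive.
    """
    if not protein:
        raise ValueError("empty protein")
    M = hmm.length
    obs = encode_protein(protein)
    L = len(obs)
    with np.errstate(divide="ignore"):
        lo_match = np.where(hmm.match_emissions > 0, np.log(hmm.match_emissions / BACKGROUND), LOG0)
        lo_ins = np.where(hmm.insert_emissions > 0, np.log(hmm.insert_emissions / BACKGROUND), LOG0)
        lt = np.where(hmm.transitions > 0, np.log(hmm.transitions), LOG0)
    entry = -math.log(M)
    exit_ = -math.log(M)

    # 0-based match state s corresponds to file node s+1; transitions out of
    # state s live in row s+1 of the node-0-based transition table
    tMM = lt[:-1, 0]  # tMM[s] = M_{s-1}->M_s uses lt[s, 0]; see vm recurrence
    tMI = lt[1:, 1]  # M_s -> I_s
    tIM = lt[:-1, 3]
    tII = lt[1:, 4]  # I_s -> I_s
    tDM = lt[:-1, 5]
    tMD = lt[1:, 2]  # M_s -> D_{s+1}
    tDD = lt[1:, 6]  # D_s -> D_{s+1}
    # prefix sums of delete-extension costs: cp[x] = sum(tDD[0:x])
    cp = np.concatenate(([0.0], np.cumsum(np.clip(tDD, LOG0, 0.0))))

    neg = np.full(M, LOG0)
    vm_prev = neg.copy()
    vi_prev = neg.copy()
    vd_prev = neg.copy()
    sm_prev = np.zeros(M, dtype=np.int64)  # start residue index of best path
    si_prev = np.zeros(M, dtype=np.int64)
    sd_prev = np.zeros(M, dtype=np.int64)

    best_score = LOG0
    best = (0, 0, 0, 0)

    for i in range(L):
        a = obs[i]
        em = lo_match[:, a] if a >= 0 else np.zeros(M)
        em_i = lo_ins[1:, a] if a >= 0 else np.zeros(M)
        # candidates for entering match state k at residue i
        cand = np.stack(
            [
                np.concatenate(([LOG0], vm_prev[:-1] + tMM[1:])),
                np.concatenate(([LOG0], vi_prev[:-1] + tIM[1:])),
                np.concatenate(([LOG0], vd_prev[:-1] + tDM[1:])),
                np.full(M, entry),
            ]
        )
        starts = np.stack(
            [
                np.concatenate(([0], sm_prev[:-1])),
                np.concatenate(([0], si_prev[:-1])),
                np.concatenate(([0], sd_prev[:-1])),
                np.full(M, i, dtype=np.int64),
            ]
        )
        choice = np.argmax(cand, axis=0)
        vm = em + np.take_along_axis(cand, choice[None, :], 0)[0]
        sm = np.take_along_axis(starts, choice[None, :], 0)[0]

        ci = np.argmax(np.stack([vm_prev + tMI, vi_prev + tII]), axis=0)
        vi = em_i + np.where(ci == 0, vm_prev + tMI, vi_prev + tII)
        si = np.where(ci == 0, sm_prev, si_prev)

        # delete states: vd[k] = max_{j<k} vm[j] + M_j->D_{j+1} + tDD(j+1 .. k-1),
        # solved in one pass with a max-prefix scan over g[j] = vm[j]+tMD[j]-cp[j+1]
        vd = neg.copy()
        sd = np.zeros(M, dtype=np.int64)
        if M > 1:
            g = vm[:-1] + tMD[:-1] - cp[1:M]
            run = np.maximum.accumulate(g)
            idx = np.maximum.accumulate(np.where(g == run, np.arange(M - 1), 0))
            vd[1:] = cp[1:M] + run
            sd[1:] = sm[idx]
        score_here = vm + exit_
        k_best = int(np.argmax(score_here))
        if score_here[k_best] > best_score:
            best_score = float(score_here[k_best])
            best = (int(sm[k_best]) + 1, i + 1, 0, k_best + 1)
        vm_prev, vi_prev, vd_prev = vm, vi, vd
        sm_prev, si_prev, sd_prev = sm, si, sd

    bits = best_score / math.log(2)
    if hmm.stats_viterbi is not None:
        mu, lam = hmm.stats_viterbi
        pval = min(1.0, math.exp(min(700.0, -lam * (bits - mu))))
    else:
        tau = math.log2(max(2, hmm.length * 400))
        pval = min(1.0, math.exp(min(700.0, -gumbel_lambda * (bits - tau))))
    e_value = n_targets * pval
    qs, qe, _, ke = best
    # first match state: recompute from span length is not reliable with gaps;
    # report the entry state as ke - (qe - qs) bounded to >= 1
    ks = max(1, ke - (qe - qs))
    return bits, e_value, (qs, qe, ks, ke)
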