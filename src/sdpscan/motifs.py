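"""Motif models, scanning, per-sequence architectures, and ZOOPS discovery.

Motifs are position weight matrices over the 20 standard residues, scored
as log2 odds against a background distribution. Scanning replaces an
external motif-search run: every window of an (ungapped) sequence is
scored and hits above a bits threshold are kept; the per-sequence
*architecture* is the greedy non-overlapping hit selection, which is what
gets compared across enzyme classes. A single-motif ZOOPS
(zero-or-one-occurrence-per-sequence) EM is included for testing planted
motifs; multi-motif discovery is delegated to external MEME.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import AMINO_ACIDS, ProteinSequence

# MEME protein alphabet order
ALPHABET = AMINO_ACIDS
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


class MotifError(ValueError):
    pass


@dataclass
class MotifModel:
    motif_id: str
    pwm: np.ndarray  # (width, 20) probability rows
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    pseudocount: float = 0.01
    nsites: int = 20

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 20:
            raise MotifError(f"motif {self.motif_id}: pwm must be (width, 20)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise MotifError(f"motif {self.motif_id}: pwm rows must sum to 1")
        if not 1 <= self.width <= 200:
            raise MotifError(f"motif {self.motif_id}: width {self.width} out of range")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise MotifError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    def smoothed_log_odds(self) -> np.ndarray:
        """(width, 20) log2-odds matrix after pseudocount smoothing."""
        p = (self.pwm + self.pseudocount) / (1.0 + 20 * self.pseudocount)
        return np.log2(p / self.background)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=1))

    def consensus_score(self) -> float:
        lo = self.smoothed_log_odds()
        return float(lo.max(axis=1).sum())

    def default_min_bits(self) -> float:
        """Consensus score minus 25% — the bundled scanning threshold."""
        return 0.75 * self.consensus_score()

    def information_content(self) -> float:
        """Total IC of the motif in bits (uniform reference)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(self.pwm > 0, self.pwm * np.log2(self.pwm), 0.0).sum(axis=1)
        return float((math.log2(20) - h).sum())


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif_id: str
    start: int  # 1-based in the ungapped sequence
    width: int
    score: float  # log-odds bits

    @property
    def end(self) -> int:
        """1-based inclusive end."""
        return self.start + self.width - 1

    def overlaps(self, other: "MotifHit") -> bool:
        return not (self.end < other.start or other.end < self.start)


@dataclass
class MotifArchitecture:
    seq_id: str
    hits: list[MotifHit]

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: h.start)
        for a, b in zip(self.hits, self.hits[1:]):
            if a.overlaps(b):
                raise MotifError(
                    f"{self.seq_id}: overlapping hits at {a.start} and {b.start}"
                )

    def motif_ids(self) -> list[str]:
        return [h.motif_id for h in self.hits]

    def covering(self, pos: int) -> MotifHit | None:
        """The hit covering 1-based ungapped position pos, if any."""
        for h in self.hits:
            if h.start <= pos <= h.end:
                return h
        return None


def motif_from_consensus(
    consensus: str, motif_id: str = "m1", weight: float = 0.9
) -> MotifModel:
    """Near-delta PWM putting ``weight`` on the consensus letter at each
    position and the remainder spread uniformly over the other 19."""
    w = len(consensus)
    pwm = np.full((w, 20), (1.0 - weight) / 19.0)
    for k, aa in enumerate(consensus):
        pwm[k, AA_INDEX[aa]] = weight
    return MotifModel(motif_id=motif_id, pwm=pwm)


# ----------------------------------------------------------- MEME minimal I/O


def read_meme_minimal(path) -> list[MotifModel]:
    """Read motifs from a MEME minimal-format text file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(ln.strip().lower().startswith("meme version") for ln in lines):
        raise MotifError(f"{path}: missing 'MEME version' line")
    background = np.full(20, 0.05)
    motifs: list[MotifModel] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("Background letter frequencies"):
            freq_tokens: list[str] = []
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                freq_tokens.extend(lines[i].split())
                i += 1
            pairs = dict(zip(freq_tokens[::2], [float(x) for x in freq_tokens[1::2]]))
            background = np.array([pairs.get(aa, 0.0) for aa in ALPHABET])
            if not np.isclose(background.sum(), 1.0, atol=1e-3):
                raise MotifError(f"{path}: background frequencies do not sum to 1")
            background = background / background.sum()
            continue
        if ln.startswith("MOTIF"):
            motif_id = ln.split()[1]
            i += 1
            # find the letter-probability line
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise MotifError(f"{path}: motif {motif_id}: no probability matrix")
            header = lines[i]
            w = None
            nsites = 20
            toks = header.replace("=", " = ").split()
            for k, t in enumerate(toks):
                if t == "w" and toks[k + 1] == "=":
                    w = int(toks[k + 2])
                if t == "nsites" and toks[k + 1] == "=":
                    nsites = int(float(toks[k + 2]))
            if w is None:
                raise MotifError(f"{path}: motif {motif_id}: no width in header")
            if not 1 <= w <= 200:
                raise MotifError(f"{path}: motif {motif_id}: width {w} out of range")
            rows = []
            i += 1
            while i < len(lines) and len(rows) < w:
                s = lines[i].strip()
                if s:
                    vals = [float(x) for x in s.split()]
                    if len(vals) != 20:
                        raise MotifError(
                            f"{path}: motif {motif_id}: row with {len(vals)} values"
                        )
                    rows.append(vals)
                i += 1
            if len(rows) != w:
                raise MotifError(f"{path}: motif {motif_id}: expected {w} rows")
            pwm = np.array(rows)
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-3):
                raise MotifError(
                    f"{path}: motif {motif_id}: rows do not sum to ~1"
                )
            pwm = pwm / pwm.sum(axis=1, keepdims=True)
            motifs.append(
                MotifModel(
                    motif_id=motif_id, pwm=pwm, background=background, nsites=nsites
                )
            )
            continue
        i += 1
    if not motifs:
        raise MotifError(f"{path}: no motifs found")
    return motifs


def write_meme_minimal(path, motifs: list[MotifModel]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 5\n\nALPHABET= " + ALPHABET + "\n\n")
        bg = motifs[0].background
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{aa} {p:.6f}" for aa, p in zip(ALPHABET, bg)) + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {m.width} "
                f"nsites= {m.nsites} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ----------------------------------------------------------------- scanning


def scan_sequence(
    seq: ProteinSequence, motif: MotifModel, min_bits: float | None = None
) -> list[MotifHit]:
    """Score every window of the sequence; return hits with score >= min_bits,
    sorted by descending score (ties: smaller start)."""
    w = motif.width
    s = seq.residues
    if len(s) < w:
        return []
    if min_bits is None:
        min_bits = motif.default_min_bits()
    lo = motif.smoothed_log_odds()
    hits: list[MotifHit] = []
    for start in range(len(s) - w + 1):
        score = 0.0
        for k in range(w):
            aa = s[start + k]
            if aa == "X":
                continue  # unknown residue contributes nothing
            score += lo[k, AA_INDEX[aa]]
        if score >= min_bits:
            hits.append(
                MotifHit(
                    seq_id=seq.id,
                    motif_id=motif.motif_id,
                    start=start + 1,
                    width=w,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


def architecture(
    seq: ProteinSequence,
    motifs: list[MotifModel],
    min_bits: float | dict[str, float] | None = None,
) -> MotifArchitecture:
    """Greedy non-overlapping hit selection by descending score.

    Ties broken by smaller start, then smaller motif_id.
    """
    all_hits: list[MotifHit] = []
    for m in motifs:
        mb = min_bits.get(m.motif_id) if isinstance(min_bits, dict) else min_bits
        all_hits.extend(scan_sequence(seq, m, mb))
    all_hits.sort(key=lambda h: (-h.score, h.start, str(h.motif_id)))
    chosen: list[MotifHit] = []
    for h in all_hits:
        if not any(h.overlaps(c) for c in chosen):
            chosen.append(h)
    return MotifArchitecture(seq_id=seq.id, hits=chosen)


def classify_motif_specificity(
    architectures: list[MotifArchitecture],
    class_of: dict[str, str],
    presence_threshold: float = 0.8,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Classify each motif as ubiquitous, exclusive to a class set,
    predominant in a class set, or mixed.

    Returns motif_id -> (category, class set); the class set is empty for
    ubiquitous/mixed. exclusive: presence >= threshold inside the set and
    exactly 0 outside; predominant: presence >= threshold inside and
    <= (1 - threshold) outside; ubiquitous: >= threshold in every class.
    """
    for arch in architectures:
        if arch.seq_id not in class_of:
            raise MotifError(f"sequence {arch.seq_id!r} has no class label")
    classes = sorted({class_of[a.seq_id] for a in architectures})
    motif_ids = sorted({h.motif_id for a in architectures for h in a.hits})
    out: dict[str, tuple[str, frozenset[str]]] = {}
    for mid in motif_ids:
        presence: dict[str, float] = {}
        for c in classes:
            members = [a for a in architectures if class_of[a.seq_id] == c]
            presence[c] = sum(
                1 for a in members if mid in a.motif_ids()
            ) / len(members)
        high = frozenset(c for c in classes if presence[c] >= presence_threshold)
        if high == frozenset(classes):
            out[mid] = ("ubiquitous", frozenset())
        elif high and all(presence[c] == 0 for c in classes if c not in high):
            out[mid] = ("exclusive", high)
        elif high and all(
            presence[c] <= 1 - presence_threshold + 1e-9
            for c in classes
            if c not in high
        ):
            out[mid] = ("predominant", high)
        else:
            out[mid] = ("mixed", frozenset())
    return out


# ---------------------------------------------------------- ZOOPS discovery


def discover_motif_zoops(
    seqs: list[ProteinSequence],
    width: int,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MotifModel:
    """Single-motif ZOOPS EM: each sequence holds zero or one motif
    occurrence at a uniform position. Best of n_starts seeded restarts by
    log-likelihood; deterministic given the seed. The log-likelihood is
    asserted non-decreasing at every EM step.
    """
    if len(seqs) < 5:
        raise MotifError("ZOOPS discovery needs >= 5 sequences")
    if any(len(s) < width for s in seqs):
        raise MotifError("width exceeds the shortest sequence")
    rng = np.random.default_rng(seed)

    # integer-encode; X mapped to a uniform mixture handled via background
    enc = [np.array([AA_INDEX.get(c, -1) for c in s.residues]) for s in seqs]
    counts = np.zeros(20)
    total = 0
    for e in enc:
        for v in e:
            if v >= 0:
                counts[v] += 1
                total += 1
    background = (counts + 1.0) / (total + 20.0)

    def window_logps(theta_log: np.ndarray, bg_log: np.ndarray, e: np.ndarray):
        """log P(window | motif) - log P(window | background) per start."""
        L = len(e)
        nw = L - width + 1
        out = np.empty(nw)
        for st in range(nw):
            tot = 0.0
            for k in range(width):
                v = e[st + k]
                if v >= 0:
                    tot += theta_log[k, v] - bg_log[v]
            out[st] = tot
        return out

    best_model = None
    best_ll = -np.inf
    bg_log = np.log(background)

    def run_em(theta, gamma):
        """EM to convergence; returns (theta, gamma, ll, expected nsites)."""
        prev_obj = -np.inf
        ll = -np.inf
        z_occ = [0.0]
        for _it in range(max_iter):
            theta_log = np.log(theta)
            ll = 0.0
            z_site = []  # per-seq posterior over start positions
            z_occ = []  # per-seq posterior of having an occurrence
            for e in enc:
                nw = len(e) - width + 1
                lratio = window_logps(theta_log, bg_log, e)
                # log P(seq, occ at st) relative to all-background
                log_occ = np.log(gamma / nw) + lratio
                log_no = math.log(1 - gamma) if gamma < 1 else -np.inf
                mx = max(log_no, log_occ.max())
                denom = math.exp(log_no - mx) + np.exp(log_occ - mx).sum()
                ll += mx + math.log(denom)
                post_occ = np.exp(log_occ - mx) / denom
                z_site.append(post_occ)
                z_occ.append(post_occ.sum())
            # the MAP objective (likelihood + Dirichlet pseudocount prior on
            # theta, which the M-step maximizes) must not decrease
            obj = ll + 0.01 * float(theta_log.sum())
            assert obj >= prev_obj - 1e-7, "EM objective decreased"
            if obj - prev_obj < tol and _it > 0:
                break
            prev_obj = obj
            # M-step
            newtheta = np.full((width, 20), 0.01)
            for e, post in zip(enc, z_site):
                for st2, p in enumerate(post):
                    if p < 1e-12:
                        continue
                    for k in range(width):
                        v = e[st2 + k]
                        if v >= 0:
                            newtheta[k, v] += p
            theta = newtheta / newtheta.sum(axis=1, keepdims=True)
            gamma = float(np.clip(np.mean(z_occ), 1e-6, 1 - 1e-6))
        return theta, gamma, ll, float(sum(z_occ))

    def shifted(theta, s):
        """Shift the motif register by s columns, background-filling."""
        out = np.tile(background, (width, 1))
        if s > 0:
            out[:-s] = theta[s:]
        elif s < 0:
            out[-s:] = theta[:s]
        else:
            out = theta.copy()
        return out / out.sum(axis=1, keepdims=True)

    for _ in range(n_starts):
        # seed the PWM from a random window of a random sequence
        si = rng.integers(len(seqs))
        st = rng.integers(len(enc[si]) - width + 1)
        theta0 = np.tile(background, (width, 1)) * 0.5
        for k in range(width):
            v = enc[si][st + k]
            if v >= 0:
                theta0[k, v] += 0.5
        theta0 = theta0 / theta0.sum(axis=1, keepdims=True)
        theta, gamma, ll, ns = run_em(theta0, 0.5)
        # phase-shift refinement: EM often converges to a shifted register
        # of the true motif; restart from nearby shifts and keep the best
        for s in (-3, -2, -1, 1, 2, 3):
            theta_s, gamma_s, ll_s, ns_s = run_em(shifted(theta, s), gamma)
            if ll_s > ll + 1e-9:
                theta, gamma, ll, ns = theta_s, gamma_s, ll_s, ns_s
        if ll > best_ll:
            best_ll = ll
            best_model = MotifModel(
                motif_id="discovered",
                pwm=theta,
                background=background,
                nsites=max(1, int(round(ns))),
            )
    return best_model


def locate_motif(
    seqs: list[ProteinSequence], motif: MotifModel
) -> dict[str, int]:
    """Best-scoring start (1-based) of the motif in each sequence."""
    out: dict[str, int] = {}
    for s in seqs:
        hits = scan_sequence(s, motif, min_bits=-np.inf)
        if hits:
            out[s.id] = hits[0].start
    return out
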