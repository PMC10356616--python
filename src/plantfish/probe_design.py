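"""SNAIL probe design and sequential-hybridization codebook construction.

A SNAIL probe set targets each transcript with pairs of DNA oligos: a
padlock probe (PLP) whose 5' arm is complementary to the 5' half of a
40-50 nt target window, and a primer whose 5' segment is complementary to
the 3' half. Hybridization of the primer to the padlock juxtaposes the
padlock's 5' and 3' termini so that ligation circularizes it; rolling-circle
amplification of the circle then produces a bright DNA nanoball (RCP)
carrying many copies of a gene-specific 20-nt barcode.

Readout is sequence-by-hybridization: in each imaging round four bridge
probes link four barcodes to four fluorescent detection oligos, one per
microscope channel, so each gene occupies exactly one (round, channel) slot
of the codebook and decoding is a pure lookup.

Design rules implemented here:

1. candidate windows are 40-50 nt with GC content 40-60%;
2. each window is split into a PLP half and a primer half of 20-25 nt with
   a fixed 2-nt gap, choosing the split whose half melting temperatures are
   jointly closest to 60 °C (each half must fall within a hard ±5 °C band);
3. windows sharing a k-mer (default k=15, either strand) with any other
   transcript in the background transcriptome are rejected;
4. four mutually non-overlapping windows are kept per gene;
5. padlock and primer carry complementary segments that close the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "TargetGene",
    "ProbeWindow",
    "SnailPair",
    "Codebook",
    "DesignConfig",
    "reverse_complement",
    "gc_fraction",
    "compute_tm",
    "scan_candidate_windows",
    "specificity_screen",
    "select_probe_set",
    "assemble_snail_pair",
    "circularization_gap",
    "build_codebook",
    "codebook_capacity",
    "design_probe_sets",
    "write_order_sheet",
    "read_order_sheet",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _validate_sequence(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name} contains non-ACGT symbols: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetGene:
    """A transcript selected for probing (uppercase ACGT, >= 60 nt)."""

    gene_id: str
    transcript: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcript", _validate_sequence(self.transcript, self.gene_id))
        if len(self.transcript) < 60:
            raise ValueError(f"{self.gene_id}: transcript shorter than 60 nt")


@dataclass(frozen=True)
class ProbeWindow:
    """A 40-50 nt target window split into PLP and primer halves.

    Coordinates are 0-based half-open on the transcript; ``plp_half`` is the
    5' half, ``primer_half`` the 3' half, separated by ``gap_nt`` unprobed
    bases. ``tm_plp`` / ``tm_primer`` are nearest-neighbor melting
    temperatures of the two halves in °C.
    """

    start: int
    end: int
    gc: float
    plp_half: str
    primer_half: str
    gap_nt: int
    tm_plp: float
    tm_primer: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tm_objective(self) -> float:
        return abs(self.tm_plp - 60.0) + abs(self.tm_primer - 60.0)

    @property
    def sequence(self) -> str:
        return self.plp_half + "N" * self.gap_nt + self.primer_half

    def overlaps(self, other: "ProbeWindow") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SnailPair:
    """One padlock + primer oligo pair with its barcode.

    ``padlock_seq`` layout (5'->3'): target arm (revcomp of the window's PLP
    half) | linker | barcode complement | linker | primer-binding arm.
    ``primer_seq`` layout (5'->3'): target segment (revcomp of the primer
    half) | splint overhang. The overhang is complementary to the two
    padlock termini so that annealing the primer to the padlock brings the
    padlock ends together with a 0-nt gap for ligation.
    """

    gene_id: str
    window: ProbeWindow
    padlock_seq: str
    primer_seq: str
    barcode_id: str


@dataclass
class DesignConfig:
    """Tunable probe-design rules (defaults follow the protocol above)."""

    window_len_min: int = 40
    window_len_max: int = 50
    gc_min: float = 0.40
    gc_max: float = 0.60
    half_len_min: int = 20
    half_len_max: int = 25
    gap_nt: int = 2
    tm_target_c: float = 60.0
    tm_tolerance_c: float = 5.0
    salt_mM: float = 50.0
    oligo_nM: float = 100.0
    n_per_gene: int = 4
    specificity_k: int = 15
    linker_5: str = "TCTCAA"
    linker_3: str = "ATTACG"
    # universal primer-binding arm at the padlock 3' end; its reverse
    # complement forms the distal half of the primer splint overhang
    anchor_arm: str = "TACGTTCAGCAA"
    splint_nt: int = 6  # padlock 5'-terminal bases echoed on the primer overhang
    barcode_len: int = 20
    bridge_len: int = 30
    detection_len: int = 15
    min_barcode_hamming: int = 8


# ---------------------------------------------------------------------------
# melting temperature (unified nearest-neighbor model)
# ---------------------------------------------------------------------------

# Unified NN parameters (SantaLucia & Hicks 2004): (dH kcal/mol, dS cal/mol/K)
# per stacked dinucleotide; complementary dinucleotides share an entry.
_NN_STEPS = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT = (0.2, -5.7)
_NN_TERM_AT = (2.2, 6.9)  # per duplex end closing in A·T
_R_GAS = 1.987  # cal/mol/K


def compute_tm(seq: str, salt_mM: float = 50.0, oligo_nM: float = 100.0) -> float:
    """Duplex melting temperature (°C) of ``seq`` against its perfect complement.

    Unified nearest-neighbor thermodynamics with the monovalent-salt entropy
    correction 0.368·(N−1)·ln[Na+] and Tm = ΔH / (ΔS + R ln C_T) for a
    non-self-complementary duplex in excess of one strand.
    """
    seq = _validate_sequence(seq)
    if not 8 <= len(seq) <= 60:
        raise ValueError(f"NN model supported for 8-60 nt, got {len(seq)} nt")
    if salt_mM <= 0 or oligo_nM <= 0:
        raise ValueError("salt and oligo concentrations must be positive")
    d_h, d_s = _NN_INIT
    for i in range(len(seq) - 1):
        h, s = _NN_STEPS[seq[i : i + 2]]
        d_h += h
        d_s += s
    for base in (seq[0], seq[-1]):
        if base in "AT":
            d_h += _NN_TERM_AT[0]
            d_s += _NN_TERM_AT[1]
    d_s += 0.368 * (len(seq) - 1) * np.log(salt_mM / 1000.0)
    return 1000.0 * d_h / (d_s + _R_GAS * np.log(oligo_nM * 1e-9)) - 273.15


class _TmPrefix:
    """O(1) substring Tm on one transcript via prefix-summed ΔH/ΔS."""

    def __init__(self, seq: str, salt_mM: float, oligo_nM: float):
        self.seq = seq
        n = len(seq)
        dh = np.zeros(n)  # dh[i], ds[i]: stack between bases i and i+1
        ds = np.zeros(n)
        for i in range(n - 1):
            dh[i], ds[i] = _NN_STEPS[seq[i : i + 2]]
        self._ch = np.concatenate([[0.0], np.cumsum(dh)])
        self._cs = np.concatenate([[0.0], np.cumsum(ds)])
        self._is_at = np.array([b in "AT" for b in seq])
        self._log_salt = np.log(salt_mM / 1000.0)
        self._log_ct = np.log(oligo_nM * 1e-9)

    def tm(self, start: int, end: int) -> float:
        n = end - start
        d_h = _NN_INIT[0] + self._ch[end - 1] - self._ch[start]
        d_s = _NN_INIT[1] + self._cs[end - 1] - self._cs[start]
        for at in (self._is_at[start], self._is_at[end - 1]):
            if at:
                d_h += _NN_TERM_AT[0]
                d_s += _NN_TERM_AT[1]
        d_s += 0.368 * (n - 1) * self._log_salt
        return 1000.0 * d_h / (d_s + _R_GAS * self._log_ct) - 273.15


# ---------------------------------------------------------------------------
# window scan, specificity, selection
# ---------------------------------------------------------------------------


def scan_candidate_windows(gene: TargetGene, config: DesignConfig | None = None) -> list[ProbeWindow]:
    """Enumerate all windows passing the GC, length, split and Tm rules.

    Every start position and window length is tried (step 1 nt). For each
    GC-passing window the split point minimizing
    |Tm(plp) − target| + |Tm(primer) − target| over all legal half lengths is
    kept; windows whose best split leaves either half outside the hard
    ±``tm_tolerance_c`` band are discarded. Returned sorted by start.
    """
    cfg = config or DesignConfig()
    seq = gene.transcript
    n = len(seq)
    if n < cfg.window_len_min:
        return []
    tm = _TmPrefix(seq, cfg.salt_mM, cfg.oligo_nM)
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])

    windows: list[ProbeWindow] = []
    for start in range(n - cfg.window_len_min + 1):
        for length in range(cfg.window_len_min, cfg.window_len_max + 1):
            end = start + length
            if end > n:
                break
            gc = (gc_cum[end] - gc_cum[start]) / length
            if not cfg.gc_min <= gc <= cfg.gc_max:
                continue
            best = None
            lo = max(cfg.half_len_min, length - cfg.gap_nt - cfg.half_len_max)
            hi = min(cfg.half_len_max, length - cfg.gap_nt - cfg.half_len_min)
            for plp_len in range(lo, hi + 1):
                split = start + plp_len
                tm_plp = tm.tm(start, split)
                tm_primer = tm.tm(split + cfg.gap_nt, end)
                obj = abs(tm_plp - cfg.tm_target_c) + abs(tm_primer - cfg.tm_target_c)
                if best is None or obj < best[0]:
                    best = (obj, plp_len, tm_plp, tm_primer)
            if best is None:
                continue
            _, plp_len, tm_plp, tm_primer = best
            if (
                abs(tm_plp - cfg.tm_target_c) > cfg.tm_tolerance_c
                or abs(tm_primer - cfg.tm_target_c) > cfg.tm_tolerance_c
            ):
                continue
            windows.append(
                ProbeWindow(
                    start=start,
                    end=end,
                    gc=gc,
                    plp_half=seq[start : start + plp_len],
                    primer_half=seq[start + plp_len + cfg.gap_nt : end],
                    gap_nt=cfg.gap_nt,
                    tm_plp=tm_plp,
                    tm_primer=tm_primer,
                )
            )
    windows.sort(key=lambda w: (w.start, w.end))
    return windows


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def specificity_screen(
    window: ProbeWindow,
    transcriptome: dict[str, str],
    target_ids: set[str] | str,
    k: int = 15,
) -> tuple[bool, list[str]]:
    """Exact shared-k-mer screen of a window against a background transcriptome.

    Fails iff any contiguous k-mer of the probed window halves (either
    strand) occurs in a transcriptome record whose id is not in
    ``target_ids``. Returns ``(passed, offending_ids)``. Conservative
    stand-in for a homology search at probe length scale.
    """
    if isinstance(target_ids, str):
        target_ids = {target_ids}
    if k > len(window.plp_half) and k > len(window.primer_half):
        raise ValueError("k exceeds both probe half lengths")
    query = _kmer_set(window.plp_half, k) | _kmer_set(window.primer_half, k)
    query |= {reverse_complement(s) for s in query}
    offenders = []
    for rec_id, seq in transcriptome.items():
        if rec_id in target_ids:
            continue
        if query & _kmer_set(seq.upper(), k):
            offenders.append(rec_id)
    return (len(offenders) == 0, offenders)


def select_probe_set(
    candidates: list[ProbeWindow], n_per_gene: int = 4
) -> tuple[list[ProbeWindow], bool]:
    """Greedily pick up to ``n_per_gene`` non-overlapping windows.

    Candidates are ranked by Tm closeness to target (ties: smaller start);
    a window is kept if it overlaps none already kept. Returns the kept
    windows sorted by start and a flag that is True when fewer than
    ``n_per_gene`` could be placed.
    """
    ranked = sorted(candidates, key=lambda w: (w.tm_objective, w.start))
    chosen: list[ProbeWindow] = []
    for win in ranked:
        if len(chosen) >= n_per_gene:
            break
        if any(win.overlaps(c) for c in chosen):
            continue
        chosen.append(win)
    chosen.sort(key=lambda w: w.start)
    return chosen, len(chosen) < n_per_gene


# ---------------------------------------------------------------------------
# oligo assembly and circularization
# ---------------------------------------------------------------------------


def assemble_snail_pair(
    gene_id: str,
    window: ProbeWindow,
    barcode: str,
    barcode_id: str,
    config: DesignConfig | None = None,
    transcript: str | None = None,
) -> SnailPair:
    """Assemble the padlock and primer oligos for one window.

    The primer's splint overhang is the padlock's first ``splint_nt`` bases
    reverse-complemented... concretely: overhang = (last ``splint_nt`` nt of
    the target PLP half) + revcomp(anchor arm), so that the padlock 5'
    terminus pairs the proximal overhang segment and the padlock 3' arm
    pairs the distal segment, meeting nick-to-nick (gap 0) for ligation.

    Raises if the barcode shares a ``specificity_k``-mer with the target
    transcript (when provided).
    """
    cfg = config or DesignConfig()
    barcode = _validate_sequence(barcode, "barcode")
    if len(barcode) != cfg.barcode_len:
        raise ValueError(f"barcode must be {cfg.barcode_len} nt")
    if transcript is not None:
        k = min(cfg.specificity_k, len(barcode))
        tx_kmers = _kmer_set(transcript.upper(), k)
        bc_kmers = _kmer_set(barcode, k) | _kmer_set(reverse_complement(barcode), k)
        if tx_kmers & bc_kmers:
            raise ValueError(f"{barcode_id} collides with the {gene_id} transcript ({k}-mer)")
    padlock = (
        reverse_complement(window.plp_half)
        + cfg.linker_5
        + reverse_complement(barcode)
        + cfg.linker_3
        + cfg.anchor_arm
    )
    # splint overhang: proximal segment pairs the padlock 5' terminus,
    # distal segment pairs the padlock 3' (anchor) arm
    overhang = reverse_complement(padlock[: cfg.splint_nt]) + reverse_complement(cfg.anchor_arm)
    primer = reverse_complement(window.primer_half) + overhang
    pair = SnailPair(
        gene_id=gene_id, window=window, padlock_seq=padlock, primer_seq=primer, barcode_id=barcode_id
    )
    gap = circularization_gap(pair)
    if gap != 0:
        raise AssertionError(f"assembled pair fails circularization (gap {gap} nt)")
    return pair


def circularization_gap(pair: SnailPair, min_arm: int = 5) -> int:
    """Simulated annealing of primer to padlock; distance between padlock ends.

    Finds the longest padlock 5'-terminal and 3'-terminal segments whose
    reverse complements occur in the primer, maps the two padlock termini to
    their paired primer positions (antiparallel geometry; every occurrence
    of each terminal segment is considered, and the site combination whose
    termini come closest is taken — where the duplex actually zips up) and
    returns the number of unpaired primer bases between the termini. 0 means
    the nick is ligatable; negative means the arms overlap (not
    circularizable); a large positive value means a terminus finds no site.
    """
    primer = pair.primer_seq
    padlock = pair.padlock_seq

    def _all_occurrences(probe: str) -> list[int]:
        hits, j = [], primer.find(probe)
        while j >= 0:
            hits.append(j)
            j = primer.find(probe, j + 1)
        return hits

    def _terminal_sites(from_5prime: bool) -> tuple[list[int], int]:
        sites: list[int] = []
        best_m = 0
        for m in range(min_arm, len(padlock) + 1):
            seg = padlock[:m] if from_5prime else padlock[len(padlock) - m :]
            hits = _all_occurrences(reverse_complement(seg))
            if not hits:
                break
            sites, best_m = hits, m
        return sites, best_m

    sites5, m5 = _terminal_sites(True)
    sites3, _ = _terminal_sites(False)
    if not sites5 or not sites3:
        return len(primer)
    # antiparallel: the padlock 5' terminal base pairs primer index j5+m5-1,
    # the 3' terminal base pairs primer index j3; gap = unpaired bases between
    gaps = [j3 - (j5 + m5 - 1) - 1 for j5 in sites5 for j3 in sites3]
    return min(gaps, key=abs)


# ---------------------------------------------------------------------------
# codebook
# ---------------------------------------------------------------------------

DEFAULT_FLUOROPHORES = {1: "AF488", 2: "AF546", 3: "AF647", 4: "AF750"}


@dataclass
class Codebook:
    """Injective map gene -> (round, channel) with all readout oligos.

    ``channel_round_limit`` records the last usable round per channel (the
    far-red fluorophore signal decays and is usable only through round 8 in
    a 14-round experiment; other channels have no limit by default).
    """

    entries: dict[str, tuple[int, int]]
    barcode_seqs: dict[str, str]
    gene_barcode: dict[str, str]
    bridge_seqs: dict[str, str]
    detection_seqs: dict[int, tuple[str, str]]
    channel_round_limit: dict[int, int] = field(default_factory=dict)

    @property
    def n_rounds(self) -> int:
        return max((r for r, _ in self.entries.values()), default=0)

    @property
    def n_channels(self) -> int:
        return max(len(self.detection_seqs), max((c for _, c in self.entries.values()), default=0))

    def gene_at(self, round_index: int, channel: int) -> str | None:
        """Inverse lookup; None when the slot is unused."""
        return self._inverse().get((round_index, channel))

    def _inverse(self) -> dict[tuple[int, int], str]:
        inv = {slot: g for g, slot in self.entries.items()}
        if len(inv) != len(self.entries):
            raise ValueError("codebook is not injective onto (round, channel) slots")
        return inv

    def slot_usable(self, round_index: int, channel: int) -> bool:
        limit = self.channel_round_limit.get(channel)
        return limit is None or round_index <= limit

    def genes(self) -> list[str]:
        return list(self.entries)


def codebook_capacity(
    n_rounds: int, n_channels: int, channel_round_limit: dict[int, int] | None = None
) -> int:
    """Number of uniquely decodable genes: Σ_channels min(n_rounds, limit)."""
    if n_rounds < 0 or n_channels < 0:
        raise ValueError("rounds and channels must be non-negative")
    limits = channel_round_limit or {}
    for ch, lim in limits.items():
        if not 1 <= ch <= n_channels:
            raise ValueError(f"limit given for unknown channel {ch}")
        if lim > n_rounds:
            raise ValueError(f"channel {ch} limit {lim} exceeds n_rounds {n_rounds}")
    return sum(min(n_rounds, limits.get(ch, n_rounds)) for ch in range(1, n_channels + 1))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_orthogonal_set(
    n: int,
    length: int,
    rng: np.random.Generator,
    min_hamming: int,
    gc_min: float = 0.40,
    gc_max: float = 0.60,
    against: list[str] | None = None,
    max_tries: int = 200_000,
) -> list[str]:
    """Seeded random search for GC-bounded oligos with pairwise Hamming >= d."""
    accepted: list[str] = []
    pool = list(against or [])
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        if len(accepted) >= n:
            break
        cand = "".join(rng.choice(bases, size=length))
        if not gc_min <= gc_fraction(cand) <= gc_max:
            continue
        if any(_hamming(cand, s[:length]) < min_hamming for s in pool if len(s) >= length):
            continue
        accepted.append(cand)
        pool.append(cand)
    if len(accepted) < n:
        raise RuntimeError(f"could not find {n} orthogonal {length}-mers (got {len(accepted)})")
    return accepted


def build_codebook(
    genes: list[str],
    n_channels: int = 4,
    n_rounds: int | None = None,
    channel_round_limit: dict[int, int] | None = None,
    config: DesignConfig | None = None,
    fluorophores: dict[int, str] | None = None,
    seed: int = 0,
) -> Codebook:
    """Assign genes to (round, channel) slots and generate readout oligos.

    Slots are filled in row-major order (round 1 channels 1..n, round 2, ...),
    skipping any slot past its channel's usable-round limit. ``n_rounds=None``
    uses the fewest rounds whose capacity holds all genes. Barcodes (20-mers),
    per-gene bridge oligos and per-channel detection oligos are generated by
    a seeded random search under GC 40-60% and pairwise Hamming >= 8.
    """
    cfg = config or DesignConfig()
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    limits = dict(channel_round_limit or {})
    if n_rounds is None:
        n_rounds = 0
        while codebook_capacity(n_rounds, n_channels, _clip_limits(limits, n_rounds)) < len(genes):
            n_rounds += 1
            if n_rounds > 10_000:
                raise RuntimeError("cannot satisfy capacity (limits too restrictive?)")
    capacity = codebook_capacity(n_rounds, n_channels, _clip_limits(limits, n_rounds))
    if len(genes) > capacity:
        raise ValueError(
            f"{len(genes)} genes exceed codebook capacity {capacity} "
            f"({n_rounds} rounds x {n_channels} channels, limits {limits or 'none'})"
        )
    slots = [
        (r, c)
        for r in range(1, n_rounds + 1)
        for c in range(1, n_channels + 1)
        if limits.get(c) is None or r <= limits[c]
    ]
    entries = dict(zip(genes, slots))

    # keyed stream: a plain default_rng(seed) would replay the same base
    # sequence as any user code seeded identically (e.g. random test
    # transcripts), making barcode/transcript k-mer collisions systematic
    rng = np.random.default_rng([seed, 0x0B5EED])
    detection = _random_orthogonal_set(
        n_channels, cfg.detection_len, rng, min(cfg.min_barcode_hamming, cfg.detection_len // 2)
    )
    barcodes = _random_orthogonal_set(len(genes), cfg.barcode_len, rng, cfg.min_barcode_hamming)
    fluors = fluorophores or DEFAULT_FLUOROPHORES
    detection_seqs = {
        ch: (detection[ch - 1], fluors.get(ch, f"dye{ch}")) for ch in range(1, n_channels + 1)
    }
    barcode_seqs = {f"BC{i + 1:03d}": bc for i, bc in enumerate(barcodes)}
    gene_barcode = dict(zip(genes, barcode_seqs))
    # bridge = 5' barcode-complementary half + 3' detection-complementary half
    half = cfg.bridge_len - cfg.detection_len
    bridge_seqs = {}
    for gene, bc_id in gene_barcode.items():
        barcode = barcode_seqs[bc_id]
        channel = entries[gene][1]
        bridge_seqs[gene] = (
            reverse_complement(barcode)[:half] + reverse_complement(detection_seqs[channel][0])
        )
    return Codebook(
        entries=entries,
        barcode_seqs=barcode_seqs,
        gene_barcode=gene_barcode,
        bridge_seqs=bridge_seqs,
        detection_seqs=detection_seqs,
        channel_round_limit=limits,
    )


def _clip_limits(limits: dict[int, int], n_rounds: int) -> dict[int, int]:
    return {ch: min(lim, n_rounds) for ch, lim in limits.items()}


# ---------------------------------------------------------------------------
# end-to-end design and I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def design_probe_sets(
    targets: dict[str, str],
    transcriptome: dict[str, str] | None = None,
    config: DesignConfig | None = None,
    codebook: Codebook | None = None,
    n_channels: int = 4,
    channel_round_limit: dict[int, int] | None = None,
    seed: int = 0,
) -> tuple[list[SnailPair], Codebook, dict[str, bool]]:
    """Full design: windows -> specificity -> selection -> codebook -> oligos.

    Returns the SNAIL pairs, the codebook and a per-gene flag set when fewer
    than ``n_per_gene`` windows could be placed.
    """
    cfg = config or DesignConfig()
    genes = [TargetGene(g, s) for g, s in targets.items()]
    if codebook is None:
        codebook = build_codebook(
            [g.gene_id for g in genes],
            n_channels=n_channels,
            channel_round_limit=channel_round_limit,
            config=cfg,
            seed=seed,
        )
    pairs: list[SnailPair] = []
    short_flags: dict[str, bool] = {}
    background = transcriptome or {}
    for gene in genes:
        candidates = scan_candidate_windows(gene, cfg)
        if background:
            candidates = [
                w
                for w in candidates
                if specificity_screen(w, background, gene.gene_id, cfg.specificity_k)[0]
            ]
        chosen, short = select_probe_set(candidates, cfg.n_per_gene)
        short_flags[gene.gene_id] = short
        bc_id = codebook.gene_barcode[gene.gene_id]
        barcode = codebook.barcode_seqs[bc_id]
        for win in chosen:
            pairs.append(
                assemble_snail_pair(gene.gene_id, win, barcode, bc_id, cfg, gene.transcript)
            )
    return pairs, codebook, short_flags


_SHEET_COLUMNS = ["name", "sequence", "type", "gene", "round", "channel"]


def write_order_sheet(pairs: list[SnailPair], codebook: Codebook, path) -> "pd.DataFrame":
    """Write one TSV row per oligo (padlock/primer/bridge/detection)."""
    import pandas as pd

    rows = []
    per_gene_counter: dict[str, int] = {}
    for pair in pairs:
        idx = per_gene_counter.get(pair.gene_id, 0) + 1
        per_gene_counter[pair.gene_id] = idx
        rnd, ch = codebook.entries[pair.gene_id]
        rows.append(
            {
                "name": f"{pair.gene_id}_PLP{idx}",
                "sequence": pair.padlock_seq,
                "type": "padlock",
                "gene": pair.gene_id,
                "round": rnd,
                "channel": ch,
            }
        )
        rows.append(
            {
                "name": f"{pair.gene_id}_PRIMER{idx}",
                "sequence": pair.primer_seq,
                "type": "primer",
                "gene": pair.gene_id,
                "round": rnd,
                "channel": ch,
            }
        )
    for gene, bridge in codebook.bridge_seqs.items():
        rnd, ch = codebook.entries[gene]
        rows.append(
            {
                "name": f"{gene}_BRIDGE",
                "sequence": bridge,
                "type": "bridge",
                "gene": gene,
                "round": rnd,
                "channel": ch,
            }
        )
    for ch, (seq, fluor) in sorted(codebook.detection_seqs.items()):
        rows.append(
            {
                "name": f"DETECT_C{ch}_{fluor}",
                "sequence": seq,
                "type": "detection",
                "gene": "",
                "round": 0,
                "channel": ch,
            }
        )
    sheet = pd.DataFrame(rows, columns=_SHEET_COLUMNS)
    sheet.to_csv(path, sep="\t", index=False)
    return sheet


def read_order_sheet(path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"gene": str})


def write_codebook_csv(codebook: Codebook, path) -> None:
    """Flat CSV: gene, round, channel, barcode_id, barcode, bridge_seq."""
    import pandas as pd

    rows = [
        {
            "gene": gene,
            "round": rnd,
            "channel": ch,
            "barcode_id": codebook.gene_barcode[gene],
            "barcode": codebook.barcode_seqs[codebook.gene_barcode[gene]],
            "bridge_seq": codebook.bridge_seqs[gene],
        }
        for gene, (rnd, ch) in codebook.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook_csv(path, channel_round_limit: dict[int, int] | None = None) -> Codebook:
    """Rebuild a (readout-oligo-less detection) Codebook from the flat CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    entries = {r.gene: (int(r.round), int(r.channel)) for r in df.itertuples()}
    barcode_seqs = {r.barcode_id: r.barcode for r in df.itertuples()}
    gene_barcode = {r.gene: r.barcode_id for r in df.itertuples()}
    bridge_seqs = {r.gene: r.bridge_seq for r in df.itertuples()}
    channels = sorted({c for _, c in entries.values()})
    detection_seqs = {ch: ("", DEFAULT_FLUOROPHORES.get(ch, f"dye{ch}")) for ch in channels}
    return Codebook(
        entries=entries,
        barcode_seqs=barcode_seqs,
        gene_barcode=gene_barcode,
        bridge_seqs=bridge_seqs,
        detection_seqs=detection_seqs,
        channel_round_limit=dict(channel_round_limit or {}),
    )
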