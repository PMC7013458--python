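"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a targeted-methylation experiment: a genome of CpG
islands (CGIs) split into an intrinsically methylated and an unmethylated
class, one unmethylated CGI designated as the sgRNA target, a ground-truth
methylome per condition, bisulfite amplicon read pairs (top strand only) and
MBD-pulldown fragment sets.

The treatment model captures the two routes by which a dCas9-SunTag /
DNMT3A-DNMT3L editor deposits methylation:

* on-target: non-blocked CpGs of the target CGI are driven to ``p_on``;
  CpGs under the dCas9-sgRNA footprint stay at baseline (sterically blocked);
* off-target: the effector binds accessible DNA on its own, so every
  unmethylated off-target CGI *r* gains ``theta * a_r * p_max`` methylation
  probability, where ``theta`` in (0, 1] is the relative untargeted
  DNA-binding affinity of the DNMT3A part (1 for wild type, lower for
  DNA-binding mutants) and ``a_r`` is the chromatin accessibility of the CGI.

Already-methylated CGIs do not change under treatment, which is what the
downstream re-calibration normalization relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._utils import find_cpg_sites, seq_to_array, stage_rng
from .bisseq import AmpliconSpec, PHRED_OFFSET
from .errors import ConfigurationError, DegenerateInputError, ParameterError
from .intervals import Interval, IntervalSet
from .io import FastqRecord

ISG15_SGRNA = "GTTCGCTGCCTCTCAGCCGC"     # guide targeting the ISG15 promoter CGI
SCRAMBLED_SGRNA = "GAACAGTCGCGTTTGCGACT"  # no-target control guide

METHYLATED, UNMETHYLATED = "methylated", "unmethylated"

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_prob(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be in [0, 1], got {value}")
    return float(value)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Knobs of the sequencing-level simulation.

    conversion_rate
        Probability that an *unmethylated* cytosine reads as T after
        bisulfite treatment (field QC expects > 0.995).
    inappropriate_conversion
        Probability that a *methylated* cytosine nevertheless reads as T.
    sequencing_error_rate
        Per-base substitution probability, applied last.
    mbd_capture_q
        Per-methylated-CpG probability that the MBD pulldown captures the
        fragment carrying it.
    """

    conversion_rate: float = 0.998
    inappropriate_conversion: float = 0.002
    sequencing_error_rate: float = 0.001
    read_length: int = 250
    n_read_pairs: int = 5000
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 30.0
    n_fragments: int = 50_000
    mbd_capture_q: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in (
            "conversion_rate",
            "inappropriate_conversion",
            "sequencing_error_rate",
            "mbd_capture_q",
        ):
            _check_prob(getattr(self, name), name)
        if self.n_read_pairs <= 0 or self.n_fragments <= 0:
            raise ParameterError("n_read_pairs and n_fragments must be positive")
        if self.read_length <= 0:
            raise ParameterError("read_length must be positive")
        if self.fragment_length_mean < 20:
            raise ParameterError("fragment_length_mean unreasonably small (< 20 bp)")


# ---------------------------------------------------------------------------
# Synthetic genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SgRNASite:
    protospacer: str
    pam: str
    chrom: str
    start: int          # 0-based start of the 20-mer
    strand: str = "+"


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    cgis: IntervalSet                    # name column holds the class label
    target_region: Interval
    sgrna: SgRNASite
    _cpg_cache: dict = field(default_factory=dict, repr=False)

    def cpg_positions(self, chrom: str) -> np.ndarray:
        if chrom not in self._cpg_cache:
            self._cpg_cache[chrom] = find_cpg_sites(self.sequences[chrom])
        return self._cpg_cache[chrom]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def validate(self) -> None:
        self.cgis.validate_within(self.chrom_sizes)
        if not self.cgis.is_disjoint():
            raise ConfigurationError("CGI intervals overlap")
        t = self.target_region
        hits = [
            i
            for i, iv in enumerate(self.cgis)
            if iv.chrom == t.chrom and iv.start < t.end and iv.end > t.start
        ]
        if len(hits) != 1:
            raise ConfigurationError(
                f"target region must overlap exactly one CGI, found {len(hits)}"
            )
        sg = self.sgrna
        found = self.sequences[sg.chrom][sg.start : sg.start + len(sg.protospacer)]
        if found != sg.protospacer:
            raise ConfigurationError("planted protospacer absent at its recorded coordinate")


def _random_dna(rng: np.random.Generator, n: int, p) -> np.ndarray:
    return rng.choice(_ACGT, size=n, p=p)


def _strip_cpgs(arr: np.ndarray) -> None:
    """Rewrite the G of every CG to A, in place (cannot create new CGs)."""
    mask = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    arr[1:][mask] = ord("A")


def make_genome(
    n_cgis: int = 60,
    cgi_length: int = 300,
    spacer_length: int = 700,
    frac_methylated: float = 0.5,
    cpg_period: int = 9,
    protospacer: str = ISG15_SGRNA,
    pam: str = "AGG",
    chrom: str = "chrS1",
    seed: int = 0,
) -> SyntheticGenome:
    """Build a single-chromosome genome of evenly spaced CGIs.

    Inter-CGI background is CpG-free (every stray CG is rewritten), so all
    methylation-capturable signal sits in CGIs; each CGI carries a planted
    CpG every ``cpg_period`` bp.  A fraction ``frac_methylated`` of CGIs is
    labelled as intrinsically methylated; the first unmethylated CGI hosts
    the sgRNA protospacer+PAM and becomes the designated target region.
    """
    if n_cgis < 2:
        raise ParameterError("need at least two CGIs")
    if cgi_length < len(protospacer) + len(pam):
        raise ParameterError("CGI too short to host the protospacer")
    rng = stage_rng(seed, "genome")
    length = n_cgis * (cgi_length + spacer_length) + spacer_length
    arr = _random_dna(rng, length, p=[0.3, 0.2, 0.2, 0.3])
    _strip_cpgs(arr)

    starts = spacer_length + np.arange(n_cgis) * (cgi_length + spacer_length)
    for s in starts:
        seg = _random_dna(rng, cgi_length, p=[0.2, 0.3, 0.3, 0.2])
        _strip_cpgs(seg)
        for off in range(2, cgi_length - 1, cpg_period):
            seg[off] = ord("C")
            seg[off + 1] = ord("G")
        arr[s : s + cgi_length] = seg

    n_meth = int(round(frac_methylated * n_cgis))
    labels = np.array([METHYLATED] * n_meth + [UNMETHYLATED] * (n_cgis - n_meth))
    rng.shuffle(labels)
    if UNMETHYLATED not in labels:
        labels[-1] = UNMETHYLATED
    target_idx = int(np.flatnonzero(labels == UNMETHYLATED)[0])

    site = protospacer + pam
    sg_start = int(starts[target_idx] + (cgi_length - len(site)) // 2)
    arr[sg_start : sg_start + len(site)] = seq_to_array(site)

    # CGI/spacer junctions can form stray CGs whose C lies outside any CGI;
    # rewrite those Cs so all CpGs sit inside CGIs (C-to-A cannot create a CG)
    cg_c = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    in_cgi = np.zeros(length, dtype=bool)
    for s in starts:
        in_cgi[s : s + cgi_length] = True
    arr[cg_c[~in_cgi[cg_c]]] = ord("A")

    cgis = IntervalSet.from_arrays(
        chrom,
        starts,
        starts + cgi_length,
        name=list(labels),
        score=np.zeros(n_cgis),
        strand=["."] * n_cgis,
    )
    genome = SyntheticGenome(
        sequences={chrom: arr.tobytes().decode()},
        cgis=cgis,
        target_region=Interval(chrom, int(starts[target_idx]), int(starts[target_idx] + cgi_length), "target"),
        sgrna=SgRNASite(protospacer, pam, chrom, sg_start, "+"),
    )
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# Ground-truth methylome
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTruth:
    """Per-CpG methylation probabilities for the untreated and treated states."""

    cpg_pos: dict[str, np.ndarray]
    probs: dict[str, dict[str, np.ndarray]]   # condition -> chrom -> probability
    blocked_sites: dict[str, np.ndarray]      # chrom -> indices into cpg_pos
    accessibility: dict[int, float]           # CGI row -> a_r (off-target unmeth CGIs)
    theta: float
    p_on: float
    p_max: float

    def condition(self, name: str) -> dict[str, np.ndarray]:
        return self.probs[name]


def simulate_methylome(
    genome: SyntheticGenome,
    theta: float,
    p_on: float = 0.84,
    seed: int = 0,
    p_max: float = 0.6,
    meth_beta: tuple[float, float] = (20.0, 2.0),
    unmeth_beta: tuple[float, float] = (1.0, 30.0),
    access_beta: tuple[float, float] = (2.0, 2.0),
) -> MethylomeTruth:
    """Draw a ground-truth methylome for the untreated and treated conditions.

    Baseline and accessibility draws come from seed streams independent of
    ``theta``, so two methylomes simulated with the same seed but different
    affinities share baselines and per-CGI accessibilities exactly — the
    treated off-target gain is then proportional to ``theta`` site by site.
    """
    if not (0.0 < theta <= 1.0):
        raise ParameterError(f"theta must be in (0, 1], got {theta}")
    _check_prob(p_on, "p_on")
    _check_prob(p_max, "p_max")
    base_rng = stage_rng(seed, "baseline")
    access_rng = stage_rng(seed, "accessibility")

    cgi_df = genome.cgis.df
    cpg_pos: dict[str, np.ndarray] = {}
    untreated: dict[str, np.ndarray] = {}
    treated: dict[str, np.ndarray] = {}
    blocked: dict[str, np.ndarray] = {}

    # accessibility for every unmethylated CGI, in genomic row order
    unmeth_rows = np.flatnonzero(cgi_df["name"].to_numpy() == UNMETHYLATED)
    access = {int(r): float(access_rng.beta(*access_beta)) for r in unmeth_rows}

    t = genome.target_region
    sg = genome.sgrna
    foot_start, foot_end = sg.start, sg.start + len(sg.protospacer) + len(sg.pam)

    for chrom in genome.sequences:
        pos = genome.cpg_positions(chrom)
        cpg_pos[chrom] = pos
        rows = cgi_df.index[cgi_df["chrom"] == chrom].to_numpy()
        starts = cgi_df.loc[rows, "start"].to_numpy()
        ends = cgi_df.loc[rows, "end"].to_numpy()
        classes = cgi_df.loc[rows, "name"].to_numpy()
        # CGIs are disjoint and sorted: map each CpG to its containing CGI
        if len(rows):
            which = np.searchsorted(starts, pos, side="right") - 1
            which_c = np.clip(which, 0, len(rows) - 1)
            in_cgi = (which >= 0) & (pos < ends[which_c])
            in_meth = in_cgi & (classes[which_c] == METHYLATED)
        else:
            which_c = np.zeros(pos.size, dtype=np.int64)
            in_cgi = np.zeros(pos.size, dtype=bool)
            in_meth = in_cgi

        base = base_rng.beta(*unmeth_beta, size=pos.size)
        base[in_meth] = base_rng.beta(*meth_beta, size=int(in_meth.sum()))
        untreated[chrom] = base

        access_vec = np.zeros(len(rows))
        for k, r in enumerate(rows):
            is_target = chrom == t.chrom and starts[k] < t.end and ends[k] > t.start
            if classes[k] == UNMETHYLATED and not is_target:
                access_vec[k] = access[int(r)]
        gain = np.where(in_cgi, theta * access_vec[which_c] * p_max, 0.0)
        gain[in_meth] = 0.0
        tr = np.clip(base + gain, 0.0, 1.0)
        if chrom == t.chrom:
            in_target = (pos >= t.start) & (pos < t.end)
            in_foot = (pos >= foot_start) & (pos < foot_end)
            blocked[chrom] = np.flatnonzero(in_target & in_foot)
            tr[in_target & ~in_foot] = p_on
            tr[in_target & in_foot] = base[in_target & in_foot]
        else:
            blocked[chrom] = np.empty(0, dtype=np.int64)
        treated[chrom] = tr

    access_offtarget = {
        r: a
        for r, a in access.items()
        if not (
            cgi_df.at[r, "chrom"] == t.chrom
            and cgi_df.at[r, "start"] < t.end
            and cgi_df.at[r, "end"] > t.start
        )
    }
    return MethylomeTruth(
        cpg_pos=cpg_pos,
        probs={"untreated": untreated, "treated": treated},
        blocked_sites=blocked,
        accessibility=access_offtarget,
        theta=theta,
        p_on=p_on,
        p_max=p_max,
    )


# ---------------------------------------------------------------------------
# Amplicon-level truth helpers
# ---------------------------------------------------------------------------

def make_amplicon(
    name: str = "ISG15_syn",
    length: int = 292,
    n_cpgs: int = 19,
    blocked_indices=(16, 17, 18, 19),
    analysis_indices=tuple(range(1, 16)),
    seed: int = 0,
) -> AmpliconSpec:
    """A synthetic amplicon reference with evenly spaced CpGs.

    Defaults mimic the geometry of a 292 bp promoter amplicon sequenced
    2 x 250: 19 CpG sites, the last four under the dCas9 footprint, sites
    1-15 entering the region average.  Background cytosines outside CpG
    context are plentiful (conversion QC needs them).
    """
    rng = stage_rng(seed, f"amplicon:{name}")
    arr = _random_dna(rng, length, p=[0.25, 0.3, 0.2, 0.25])
    _strip_cpgs(arr)
    offsets = np.linspace(4, length - 4, n_cpgs).astype(int)
    if np.diff(offsets).min() < 2:
        raise ParameterError("amplicon too short for requested CpG count")
    for off in offsets:
        arr[off] = ord("C")
        arr[off + 1] = ord("G")
    return AmpliconSpec(
        name=name,
        sequence=arr.tobytes().decode(),
        cpg_offsets=tuple(int(o) for o in offsets),
        blocked_indices=frozenset(blocked_indices),
        analysis_indices=tuple(analysis_indices),
    )


def amplicon_baseline_probs(
    amplicon: AmpliconSpec, seed: int = 0, unmeth_beta: tuple[float, float] = (1.0, 30.0)
) -> np.ndarray:
    """Untreated per-CpG probabilities for an unmethylated promoter CGI."""
    rng = stage_rng(seed, f"amplicon-baseline:{amplicon.name}")
    return rng.beta(*unmeth_beta, size=amplicon.n_cpgs)


def treated_target_probs(
    baseline: np.ndarray, amplicon: AmpliconSpec, p_on: float
) -> np.ndarray:
    """Target-amplicon treatment: non-blocked CpGs to p_on, blocked stay at baseline."""
    _check_prob(p_on, "p_on")
    probs = np.asarray(baseline, dtype=float).copy()
    blocked = np.array([i - 1 for i in sorted(amplicon.blocked_indices)], dtype=int)
    mask = np.ones(amplicon.n_cpgs, dtype=bool)
    if blocked.size:
        mask[blocked] = False
    probs[mask] = p_on
    return probs


def treated_offtarget_probs(
    baseline: np.ndarray, theta: float, accessibility: float, p_max: float = 0.6
) -> np.ndarray:
    """Off-target gain model: baseline + theta * a * p_max, clipped to [0, 1]."""
    if not (0.0 < theta <= 1.0):
        raise ParameterError(f"theta must be in (0, 1], got {theta}")
    _check_prob(accessibility, "accessibility")
    _check_prob(p_max, "p_max")
    return np.clip(np.asarray(baseline, dtype=float) + theta * accessibility * p_max, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Bisulfite amplicon reads
# ---------------------------------------------------------------------------

def simulate_bisulfite_reads(
    amplicon: AmpliconSpec,
    site_probs: np.ndarray,
    params: SimulationParams,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Paired bisulfite reads from the top strand of one amplicon.

    Each fragment spans the whole amplicon.  Per fragment, every CpG
    cytosine is methylated with its site probability; unmethylated Cs (CpG
    or not) read as T with ``conversion_rate`` and methylated Cs with
    ``inappropriate_conversion``.  Substitution errors are applied to the
    emitted reads last; mate 2 is the reverse complement of the fragment 3'
    end.  Qualities are constant Q37.
    """
    site_probs = np.asarray(site_probs, dtype=float)
    if site_probs.shape != (amplicon.n_cpgs,):
        raise ParameterError("site_probs must have one entry per amplicon CpG")
    if ((site_probs < 0) | (site_probs > 1)).any():
        raise ParameterError("site probabilities must be in [0, 1]")
    ref = seq_to_array(amplicon.sequence)
    L = ref.size
    rl = params.read_length
    if L < rl:
        raise ConfigurationError(f"amplicon {amplicon.name} ({L} bp) shorter than read length {rl}")

    rng = stage_rng(params.seed, f"bisulfite:{amplicon.name}")
    n = params.n_read_pairs

    frag = np.broadcast_to(ref, (n, L)).copy()
    cpg_cols = np.asarray(amplicon.cpg_offsets, dtype=np.int64)
    non_cpg_c = amplicon.non_cpg_c_offsets()

    meth = rng.random((n, cpg_cols.size)) < site_probs[None, :]
    u = rng.random((n, cpg_cols.size))
    to_t_cpg = np.where(meth, u < params.inappropriate_conversion, u < params.conversion_rate)
    sub = frag[:, cpg_cols]
    sub[to_t_cpg] = _T_CODE
    frag[:, cpg_cols] = sub

    if non_cpg_c.size:
        to_t = rng.random((n, non_cpg_c.size)) < params.conversion_rate
        sub = frag[:, non_cpg_c]
        sub[to_t] = _T_CODE
        frag[:, non_cpg_c] = sub

    r1 = frag[:, :rl].copy()
    r2 = _revcomp_matrix(frag[:, L - rl :])
    for mat in (r1, r2):
        _apply_sequencing_errors(mat, params.sequencing_error_rate, rng)

    qual = "F" * rl  # Phred 37
    recs1 = [FastqRecord(f"{amplicon.name}:frag{i}/1", r1[i].tobytes().decode(), qual) for i in range(n)]
    recs2 = [FastqRecord(f"{amplicon.name}:frag{i}/2", r2[i].tobytes().decode(), qual) for i in range(n)]
    return recs1, recs2


_T_CODE = ord("T")
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[mat[:, ::-1]]


def _apply_sequencing_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Substitute each base with one of the three others with probability ``rate``."""
    if rate <= 0:
        return
    err = rng.random(mat.shape) < rate
    idx = np.flatnonzero(err)
    if idx.size == 0:
        return
    flat = mat.reshape(-1)
    base_idx = np.searchsorted(_ACGT, flat[idx])
    shift = rng.integers(1, 4, size=idx.size)
    flat[idx] = _ACGT[(base_idx + shift) % 4]


def inject_low_quality_tails(
    records: list[FastqRecord], tail_length: int, tail_quality: int = 2
) -> list[FastqRecord]:
    """Testing hook: overwrite the last ``tail_length`` quality scores with a
    low value so the 3' quality-trimming path has something to remove."""
    ch = chr(tail_quality + PHRED_OFFSET)
    out = []
    for rec in records:
        k = min(tail_length, len(rec.qual))
        out.append(FastqRecord(rec.name, rec.seq, rec.qual[: len(rec.qual) - k] + ch * k))
    return out


# ---------------------------------------------------------------------------
# MBD-pulldown fragments
# ---------------------------------------------------------------------------

def simulate_mbd_fragments(
    genome: SyntheticGenome,
    truth: MethylomeTruth,
    params: SimulationParams,
    condition: str = "treated",
) -> IntervalSet:
    """MBD-enriched fragment set under the capture model.

    Candidate fragments are drawn uniformly over the genome with Gaussian
    lengths; a fragment is retained with probability
    ``1 - prod_i(1 - q * p_i)`` over the CpGs it covers — the marginal of a
    per-site Bernoulli methylation state followed by a Bernoulli(q) capture
    per methylated CpG.  Exactly ``n_fragments`` retained fragments are
    emitted, in retention order.
    """
    q = params.mbd_capture_q
    probs = truth.condition(condition)
    chroms = list(genome.sequences)
    n_cpgs_total = sum(genome.cpg_positions(c).size for c in chroms)
    if n_cpgs_total == 0:
        raise DegenerateInputError("genome contains no CpGs")
    max_p = max(float(probs[c].max()) if probs[c].size else 0.0 for c in chroms)
    if q <= 0 or max_p <= 0:
        raise DegenerateInputError(
            "capture model retains nothing (q = 0 or all site probabilities 0): empty enrichment"
        )

    # prefix sums of log(1 - q * p) per chromosome -> O(1) keep-prob per fragment
    log_keep: dict[str, np.ndarray] = {}
    for c in chroms:
        lk = np.log1p(-np.clip(q * probs[c], 0.0, 1.0 - 1e-12))
        log_keep[c] = np.concatenate([[0.0], np.cumsum(lk)])

    sizes = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    rng = stage_rng(params.seed, "mbd-fragments")

    kept_chrom: list[str] = []
    kept_start: list[np.ndarray] = []
    kept_end: list[np.ndarray] = []
    n_kept = 0
    attempts = 0
    batch = max(4 * params.n_fragments, 10_000)
    while n_kept < params.n_fragments:
        attempts += 1
        if attempts > 200:
            raise DegenerateInputError(
                f"retention too rare: {n_kept}/{params.n_fragments} fragments after {attempts} batches"
            )
        ci = rng.choice(len(chroms), size=batch, p=weights)
        flen = np.maximum(
            20, rng.normal(params.fragment_length_mean, params.fragment_length_sd, size=batch)
        ).astype(np.int64)
        u = rng.random(batch)
        keep_u = rng.random(batch)
        for k, c in enumerate(chroms):
            mask = ci == k
            if not mask.any():
                continue
            L = len(genome.sequences[c])
            fl = np.minimum(flen[mask], L)
            start = (u[mask] * (L - fl + 1)).astype(np.int64)
            end = start + fl
            pos = genome.cpg_positions(c)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            pk = 1.0 - np.exp(log_keep[c][hi] - log_keep[c][lo])
            sel = keep_u[mask] < pk
            if sel.any():
                kept_chrom.extend([c] * int(sel.sum()))
                kept_start.append(start[sel])
                kept_end.append(end[sel])
                n_kept += int(sel.sum())

    starts = np.concatenate(kept_start)[: params.n_fragments]
    ends = np.concatenate(kept_end)[: params.n_fragments]
    chrom_col = kept_chrom[: params.n_fragments]
    names = [f"frag_{i}" for i in range(params.n_fragments)]
    return IntervalSet.from_arrays(chrom_col, starts, ends, name=names, strand=["+"] * len(names))
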