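"""Synthetic UV-damage/repair experiments with the statistical structure the
analysis assumes.

Emulated pieces: random genomes; non-overlapping gene/dyad/TFBS annotations;
dipyrimidine-specific Poisson lesion induction; per-lesion exponential
(memoryless) repair with strand-, nucleosome- and TFBS-dependent rates;
read generation that inverts the lesion-calling convention exactly;
Poisson-cleavage alkaline-gel lanes; and strand-biased passaging mutations.

All generators are deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, gene_body, template_strand
from .genome import Genome
from .tracks import STRANDS, LesionTrack

# CPD induction is strongly skewed toward TT; exact propensities are free
# parameters of the simulator (no published per-dinucleotide values are
# assumed).
DEFAULT_DINUC_PROPENSITY = {"TT": 1.0, "TC": 0.35, "CT": 0.25, "CC": 0.10}

#: Canonical strain labels: genotype (WT, rad14, rad14phr1) x photoreactivation.
STRAIN_LABELS = (
    "WT+PR",
    "WT-PR",
    "rad14+PR",
    "rad14-PR",
    "rad14phr1+PR",
    "rad14phr1-PR",
)


def _norm_strain(strain: str) -> str:
    s = strain.replace("Δ", "").replace("delta", "").replace(" ", "")
    if s not in STRAIN_LABELS:
        raise ValueError(f"unknown strain label {strain!r}; expected one of {STRAIN_LABELS}")
    return s


# ---------------------------------------------------------------------------
# genome and annotations
# ---------------------------------------------------------------------------

def make_genome(seed: int, n_chrom: int = 1, length: int = 100_000, gc: float = 0.40) -> Genome:
    """Random genome with i.i.d. bases at the requested GC fraction."""
    if length < 1000:
        raise ValueError("chromosome length must be >= 1000")
    if not (0.0 <= gc < 1.0):
        raise ValueError("gc must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    seqs = {}
    for i in range(n_chrom):
        seqs[f"chr{i + 1}"] = "".join(rng.choice(bases, size=length, p=p))
    return Genome(seqs, seed=seed)


def _place_intervals(rng, length: int, n: int, width: int, margin: int, occupied: list,
                     max_tries: int = 20000) -> list[int]:
    """Place n interval start points of given width, >= margin from chromosome
    ends and non-overlapping with previously occupied intervals."""
    starts = []
    tries = 0
    lo, hi = margin + 1, length - margin - width
    if hi <= lo:
        raise ValueError("infeasible packing: chromosome too short for requested features")
    while len(starts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"infeasible packing: placed {len(starts)}/{n} features after {max_tries} tries"
            )
        s = int(rng.integers(lo, hi))
        iv = (s, s + width - 1)
        if any(not (iv[1] < a or iv[0] > b) for a, b in occupied):
            continue
        occupied.append(iv)
        starts.append(s)
    return starts


def make_annotations(
    genome: Genome,
    n_genes: int = 40,
    n_dyads: int = 200,
    tf_specs: list[dict] | None = None,
    seed: int = 0,
    gene_rates: np.ndarray | list | None = None,
    gene_length: tuple[int, int] = (700, 1400),
    dyad_scores: np.ndarray | list | None = None,
    intergenic_gap: int = 400,
) -> AnnotationSet:
    """Random non-overlapping genes, nucleosome dyads and TFBS.

    Gene transcription rates (mRNA/h) default to a log-uniform draw over
    0.05-40 so both the >10 (high) and <1 (low) stratification cohorts are
    populated; pass ``gene_rates`` to fix them (cycled over genes).  Dyad
    scores default to an exponential draw (mean 4) so the score>5 filter
    splits the set; pass ``dyad_scores`` to fix them.  ``tf_specs`` is a list
    of dicts ``{"tf": name, "n_sites": int, "occupancy": value-or-list}``.
    ``intergenic_gap`` sets the minimum gene spacing (actual gaps jitter up
    to twice that); small values give yeast-like genic density.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    lengths = genome.lengths
    if intergenic_gap < 1:
        raise ValueError("intergenic_gap must be >= 1")

    # genes: sequential placement with jittered gaps (supports dense packing)
    gene_rows = []
    per_chrom = np.array_split(np.arange(n_genes), len(chroms))
    for chrom, idxs in zip(chroms, per_chrom):
        cursor = 95
        for _ in idxs:
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            gap = int(rng.integers(intergenic_gap, 2 * intergenic_gap + 1))
            start = cursor + gap
            end = start + glen - 1
            if end > lengths[chrom] - 95:
                raise ValueError(
                    f"infeasible packing: {len(idxs)} genes do not fit on {chrom}"
                )
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, tes = start, end
            else:
                tss, tes = end, start
            gene_rows.append((chrom, tss, tes, strand))
    if gene_rates is None:
        rates = np.exp(rng.uniform(np.log(0.05), np.log(40), size=n_genes))
    else:
        rates = np.resize(np.asarray(gene_rates, dtype=float), n_genes)
    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "tes", "strand"])
    genes["rate_mrna_per_h"] = rates

    # dyads: jittered regular array (nucleosome repeat), >= 165 bp apart,
    # >= 95 bp from chromosome ends
    dyad_rows = []
    per_chrom_d = np.array_split(np.arange(n_dyads), len(chroms))
    dyad_occ: dict[str, list] = {c: [] for c in chroms}
    min_repeat = 165
    for chrom, idxs in zip(chroms, per_chrom_d):
        n = len(idxs)
        if n == 0:
            continue
        span = lengths[chrom] - 2 * 95 - min_repeat
        spacing = span // n
        if spacing < min_repeat:
            raise ValueError(
                f"infeasible packing: {n} dyads need repeat >= {min_repeat} bp on {chrom}"
            )
        jitter = rng.integers(0, spacing - min_repeat + 1, size=n)
        for i in range(n):
            pos = 95 + i * spacing + int(jitter[i]) + 82
            dyad_rows.append((chrom, pos))
            dyad_occ[chrom].append((pos - 82, pos + 82))
    if dyad_scores is None:
        scores = rng.exponential(scale=4.0, size=n_dyads)
    else:
        scores = np.resize(np.asarray(dyad_scores, dtype=float), n_dyads)
    dyads = pd.DataFrame(dyad_rows, columns=["chrom", "pos"])
    dyads["score"] = scores

    # TFBS: away from dyads (clear flanks) and >= 1100 bp from ends so the
    # telomere-exclusion filter is exercised by explicit placement, not luck
    tf_rows = []
    if tf_specs:
        tf_occ = {c: list(dyad_occ[c]) for c in chroms}
        for spec in tf_specs:
            n_sites = int(spec["n_sites"])
            occs = np.resize(np.asarray(spec.get("occupancy", 50.0), dtype=float), n_sites)
            chrom_pick = rng.choice(len(chroms), size=n_sites)
            for i in range(n_sites):
                chrom = chroms[int(chrom_pick[i])]
                s = _place_intervals(
                    rng, lengths[chrom], 1, width=210, margin=1100, occupied=tf_occ[chrom]
                )[0]
                strand = "+" if rng.random() < 0.5 else "-"
                tf_rows.append((spec["tf"], chrom, s + 105, strand, occs[i]))
    tfbs = pd.DataFrame(tf_rows, columns=["tf", "chrom", "midpoint", "strand", "occupancy"])

    ann = AnnotationSet(genes=genes, dyads=dyads, tfbs=tfbs)
    ann.validate(genome)
    return ann


# ---------------------------------------------------------------------------
# damage induction
# ---------------------------------------------------------------------------

def simulate_damage(
    genome: Genome,
    dose_scale: float,
    dinuc_propensity: dict[str, float] | None = None,
    seed: int = 0,
    end_margin: int = 60,
) -> LesionTrack:
    """Independent Poisson lesion counts at every dipyrimidine.

    Mean count at a site = ``dose_scale * propensity[dinucleotide]``; zero at
    non-dipyrimidines (structurally).  Sites within ``end_margin`` bp of a
    chromosome end are left undamaged: lesions there could never be observed
    by the sequencing assay (no room for a read), so excluding them keeps the
    lesions -> reads -> calling round trip an exact identity.
    """
    prop = dict(DEFAULT_DINUC_PROPENSITY if dinuc_propensity is None else dinuc_propensity)
    if any(v < 0 for v in prop.values()):
        raise ValueError("dinucleotide propensities must be >= 0")
    if dose_scale < 0:
        raise ValueError("dose_scale must be >= 0")
    rng = np.random.default_rng(seed)
    track = LesionTrack.zeros(genome, kind="damage", dose_scale=dose_scale)
    for chrom in genome.chrom_names:
        b = genome.bytes(chrom)
        for strand in STRANDS:
            mask = genome.dipy_mask(chrom, strand).copy()
            if end_margin > 0:
                mask[:end_margin] = False
                mask[-end_margin:] = False
            idx = np.nonzero(mask)[0]
            if len(idx) == 0:
                continue
            if strand == "+":
                dinucs = np.char.add(b[idx].astype("U1"), b[idx + 1].astype("U1"))
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                dinucs = np.array(
                    [comp[y] + comp[x]
                     for x, y in zip(b[idx - 1].astype("U1"), b[idx].astype("U1"))]
                )
            means = dose_scale * np.array([prop.get(d, 0.0) for d in dinucs])
            track.counts[(chrom, strand)][idx] = rng.poisson(means)
    return track


# ---------------------------------------------------------------------------
# repair kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepairRateModel:
    """Context-dependent per-lesion repair rates (per minute).

    A lesion at position/strand ``i`` survives to time t with probability
    exp(-k_i t), with k_i = k_photolyase(i) + k_NER(i).  Photolyase repair is
    attenuated on the transcribed strand in gene bodies (``ts_occlusion``,
    RNA-Pol-II occlusion), inside nucleosomes (translational profile,
    ~10.3-bp rotational-setting modulation, extra 3'-side attenuation), and
    at occupied TF binding sites (``tfbs_block``).  NER is boosted on the
    transcribed strand (``ner_ts_boost``, TC-NER).

    Base rates default to single-pathway gel regimes: photolyase 0.0175/min
    (≈65% of CPDs removed in 60 min when acting alone) and NER 0.0029/min
    (≈16% in 60 min).
    """

    base_rate_photolyase: float = 0.0175
    base_rate_ner: float = 0.0029
    ts_occlusion: float = 0.45
    ner_ts_boost: float = 2.0
    nuc_translational_depth: float = 0.5
    nuc_rotational_amp: float = 0.0
    nuc_rotational_period: float = 10.3
    nuc_rotational_phase: float = 0.0
    nuc_3prime_attenuation: float = 1.0
    tfbs_block: float = 0.0
    tfbs_core_halfwidth: int = 4
    tfbs_extension: int = 5
    tfbs_min_occupancy: float = 10.0
    tfbs_occupancy_saturation: float = 50.0
    nuc_half_width: int = 73

    def __post_init__(self):
        if self.base_rate_photolyase < 0 or self.base_rate_ner < 0:
            raise ValueError("base rates must be >= 0")
        if not (0 < self.ts_occlusion <= 1):
            raise ValueError("ts_occlusion must be in (0, 1]")
        if self.ner_ts_boost < 1:
            raise ValueError("ner_ts_boost must be >= 1")
        for name in ("nuc_3prime_attenuation",):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 <= self.tfbs_block <= 1):
            raise ValueError("tfbs_block must be in [0, 1]")
        if not (0 <= self.nuc_rotational_amp < 1):
            raise ValueError("nuc_rotational_amp must be in [0, 1)")

    def nucleosome_factor(self, offsets: np.ndarray, strand: str) -> np.ndarray:
        """Multiplicative photolyase-rate factor over plus-coordinate dyad
        offsets for one strand.

        The nucleosome's pseudo-dyad two-fold symmetry maps (plus strand,
        offset +o) onto (minus strand, offset -o), so all modulation is
        defined on the strand-frame offset o' = +o (plus) / -o (minus):
        a symmetric translational dip (deepest at the dyad, vanishing at the
        core edges), a rotational-setting cosine of the given period/phase,
        and the extra 3'-side attenuation for o' > 0.
        """
        w = self.nuc_half_width
        o = offsets if strand == "+" else -offsets  # strand 5'->3' frame
        trans = 1.0 - self.nuc_translational_depth * 0.5 * (1 + np.cos(np.pi * o / w))
        rot = 1.0 + self.nuc_rotational_amp * np.cos(
            2 * np.pi * (o - self.nuc_rotational_phase) / self.nuc_rotational_period
        )
        three_prime = np.where(o > 0, self.nuc_3prime_attenuation, 1.0)
        factor = np.clip(trans * rot, 0.02, None) * three_prime
        return np.where(np.abs(o) <= w, factor, 1.0)


def pathway_activity(strain: str) -> tuple[bool, bool]:
    """(photolyase_active, ner_active) for a canonical strain label."""
    s = _norm_strain(strain)
    photolyase = s.endswith("+PR") and "phr1" not in s
    ner = not s.startswith("rad14")
    return photolyase, ner


def rate_field(
    genome: Genome,
    annotations: AnnotationSet,
    model: RepairRateModel,
    strain: str,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-position, per-strand total repair rate k (per minute)."""
    photolyase_on, ner_on = pathway_activity(strain)
    kp_base = model.base_rate_photolyase if photolyase_on else 0.0
    kn_base = model.base_rate_ner if ner_on else 0.0

    fields = {}
    phot_factor = {
        (c, s): np.ones(L, dtype=float)
        for c, L in genome.lengths.items()
        for s in STRANDS
    }
    ner_factor = {k: np.ones_like(v) for k, v in phot_factor.items()}

    # transcribed-strand effects within gene bodies
    for _, gene in annotations.genes.iterrows():
        lo, hi = gene_body(gene)
        ts = template_strand(gene["strand"])
        phot_factor[(gene["chrom"], ts)][lo - 1 : hi] *= model.ts_occlusion
        ner_factor[(gene["chrom"], ts)][lo - 1 : hi] *= model.ner_ts_boost

    # nucleosome effects (photolyase accessibility)
    w = model.nuc_half_width
    offsets = np.arange(-w, w + 1)
    strand_prof = {s: model.nucleosome_factor(offsets, s) for s in STRANDS}
    for _, dyad in annotations.dyads.iterrows():
        chrom, pos = dyad["chrom"], int(dyad["pos"])
        L = genome.lengths[chrom]
        lo = max(pos - w, 1)
        hi = min(pos + w, L)
        sl = slice(lo - 1, hi)
        win = slice(lo - pos + w, hi - pos + w + 1)
        for s in STRANDS:
            phot_factor[(chrom, s)][sl] *= strand_prof[s][win]

    # TFBS block (photolyase), occupancy-scaled, core +/- extension
    half = model.tfbs_core_halfwidth + model.tfbs_extension
    for _, site in annotations.tfbs.iterrows():
        occ = float(site.get("occupancy", 0.0))
        if occ < model.tfbs_min_occupancy or model.tfbs_block == 0:
            continue
        scale = min(1.0, occ / model.tfbs_occupancy_saturation)
        factor = 1.0 - model.tfbs_block * scale
        chrom, mid = site["chrom"], int(site["midpoint"])
        L = genome.lengths[chrom]
        sl = slice(max(mid - half, 1) - 1, min(mid + half, L))
        phot_factor[(chrom, "+")][sl] *= factor
        phot_factor[(chrom, "-")][sl] *= factor

    for key in phot_factor:
        fields[key] = kp_base * phot_factor[key] + kn_base * ner_factor[key]
    return fields


@dataclass
class SimExperiment:
    """One simulated repair time course for one strain."""

    lesions_t0: LesionTrack
    surviving_lesions: dict[float, LesionTrack]
    true_fraction_remaining: dict[float, float]
    config: dict = field(default_factory=dict)


def simulate_repair(
    lesions_t0: LesionTrack,
    model: RepairRateModel,
    annotations: AnnotationSet,
    timepoints: list[float],
    strain: str,
    seed: int = 0,
) -> SimExperiment:
    """Thin each lesion independently with survival exp(-k_i t)."""
    if any(t < 0 for t in timepoints):
        raise ValueError("timepoints must be >= 0")
    strain = _norm_strain(strain)
    rng = np.random.default_rng(seed)
    genome = lesions_t0.genome
    k = rate_field(genome, annotations, model, strain)
    surviving: dict[float, LesionTrack] = {}
    frac: dict[float, float] = {}
    n0_total = lesions_t0.N
    for t in timepoints:
        trk = LesionTrack.zeros(genome, strain=strain, timepoint=t)
        for key, n0 in lesions_t0.counts.items():
            p = np.exp(-k[key] * t)
            trk.counts[key] = rng.binomial(n0, p)
        surviving[t] = trk
        frac[t] = trk.N / n0_total if n0_total else 0.0
    return SimExperiment(
        lesions_t0=lesions_t0,
        surviving_lesions=surviving,
        true_fraction_remaining=frac,
        config={"strain": strain, "timepoints": list(timepoints), "model": model, "seed": seed},
    )


# ---------------------------------------------------------------------------
# read generation (inverse of lesion calling)
# ---------------------------------------------------------------------------

def lesions_to_reads(
    surviving: LesionTrack,
    background_nondipy_reads: float = 0.0,
    read_length: int = 50,
    seed: int = 0,
    name: str = "read",
) -> tuple[pd.DataFrame, int]:
    """Emit one aligned read per lesion occurrence, placed so lesion calling
    recovers the lesion exactly, plus decoy reads whose upstream dinucleotide
    is not a dipyrimidine.

    Returns (BED-like DataFrame with 0-based half-open coordinates, number of
    lesions skipped because no read fits on the chromosome).  The decoy count
    is ``round(n_real * b / (1 - b))`` so decoys make up fraction ``b`` of
    all emitted reads.
    """
    b = background_nondipy_reads
    if not (0.0 <= b <= 0.5):
        raise ValueError("background_nondipy_reads must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    genome = surviving.genome
    rows_chrom, rows_start, rows_end, rows_strand = [], [], [], []
    skipped = 0
    for (chrom, lesion_strand), arr in surviving.counts.items():
        L = genome.lengths[chrom]
        idx = np.nonzero(arr)[0]
        if len(idx) == 0:
            continue
        keys = np.repeat(idx + 1, arr[idx])  # 1-based lesion keys, one per count
        if lesion_strand == "-":
            # minus lesion keyed k covers plus (k-1, k): plus-strand read with
            # 5' end at k+1, spanning [k+1, k+read_length]
            fits = keys + read_length <= L
            skipped += int((~fits).sum())
            keys = keys[fits]
            starts = keys  # 0-based start = (k+1) - 1
            ends = keys + read_length
            strand = "+"
        else:
            # plus lesion keyed k covers (k, k+1): minus-strand read with
            # 5' end at k-1, spanning [k-read_length, k-1]
            fits = keys - read_length >= 1
            skipped += int((~fits).sum())
            keys = keys[fits]
            starts = keys - read_length - 1
            ends = keys - 1
            strand = "-"
        rows_chrom.append(np.full(len(keys), chrom, dtype=object))
        rows_start.append(starts)
        rows_end.append(ends)
        rows_strand.append(np.full(len(keys), strand, dtype=object))

    n_real = int(sum(len(a) for a in rows_start))
    n_decoy = int(round(n_real * b / (1 - b))) if b > 0 else 0
    if n_decoy:
        chroms = genome.chrom_names
        weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        # per (chrom, read strand): keys whose called dinucleotide is NOT a
        # dipyrimidine and whose read fits on the chromosome
        eligible = {}
        for chrom in chroms:
            L = genome.lengths[chrom]
            b_arr = genome.bytes(chrom)
            no_n = b_arr != b"N"
            for read_strand, lesion_strand in (("+", "-"), ("-", "+")):
                ok = ~genome.dipy_mask(chrom, lesion_strand)
                if lesion_strand == "-":
                    # key k: window is plus coords (k-1, k)
                    ok = ok & no_n & np.roll(no_n, 1)
                    pos = np.nonzero(ok)[0] + 1
                    pos = pos[(pos >= 2) & (pos + read_length <= L)]
                else:
                    # key k: window is plus coords (k, k+1)
                    ok = ok & no_n & np.roll(no_n, -1)
                    pos = np.nonzero(ok)[0] + 1
                    pos = pos[(pos - read_length >= 1) & (pos + 1 <= L)]
                eligible[(chrom, read_strand)] = pos
        for _ in range(n_decoy):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            read_strand = "+" if rng.random() < 0.5 else "-"
            pos_arr = eligible[(chrom, read_strand)]
            key = int(pos_arr[rng.integers(len(pos_arr))])
            if read_strand == "+":
                start, end = key, key + read_length
            else:
                start, end = key - read_length - 1, key - 1
            rows_chrom.append(np.array([chrom], dtype=object))
            rows_start.append(np.array([start]))
            rows_end.append(np.array([end]))
            rows_strand.append(np.array([read_strand], dtype=object))

    reads = pd.DataFrame(
        {
            "chrom": np.concatenate(rows_chrom) if rows_chrom else [],
            "start": np.concatenate(rows_start).astype(np.int64) if rows_start else [],
            "end": np.concatenate(rows_end).astype(np.int64) if rows_end else [],
            "name": name,
            "score": 0,
            "strand": np.concatenate(rows_strand) if rows_strand else [],
        }
    )
    # deterministic shuffle so the file is not sorted by lesion position
    if len(reads):
        reads = reads.iloc[rng.permutation(len(reads))].reset_index(drop=True)
    return reads, skipped


# ---------------------------------------------------------------------------
# alkaline gel lanes
# ---------------------------------------------------------------------------

def simulate_gel_lanes(
    true_density: dict[float, float],
    molecule_length: int = 50_000,
    n_molecules: int = 10_000,
    seed: int = 0,
):
    """Poisson-cleavage fragment-length samples per timepoint.

    For each timepoint with density phi (CPDs/kb), each molecule receives
    Poisson(phi * L / 1000) breaks at uniform positions; the T4-endoV lane
    holds the resulting fragment lengths and the mock lane holds uncleaved
    molecules.  Returns a list of :class:`photorepair.gel.GelLane`.
    """
    from .gel import GelLane

    rng = np.random.default_rng(seed)
    lanes = []
    for t, phi in true_density.items():
        if phi < 0:
            raise ValueError("density must be >= 0")
        lam = phi * molecule_length / 1000.0
        n_breaks = rng.poisson(lam, size=n_molecules)
        total = int(n_breaks.sum())
        if total:
            u = rng.random(total) * molecule_length
            mol = np.repeat(np.arange(n_molecules), n_breaks)
            pts = np.sort(np.concatenate([mol * molecule_length + u,
                                          np.arange(n_molecules + 1) * molecule_length * 1.0]))
            lengths = np.diff(pts)
            lengths = lengths[lengths > 0]
        else:
            lengths = np.full(n_molecules, float(molecule_length))
        lanes.append(GelLane(lane=f"t4_{t}", treatment="t4", timepoint=t,
                             fragment_lengths=lengths))
        lanes.append(GelLane(lane=f"mock_{t}", treatment="mock", timepoint=t,
                             fragment_lengths=np.full(n_molecules, float(molecule_length))))
    return lanes


# ---------------------------------------------------------------------------
# passaging mutations
# ---------------------------------------------------------------------------

_PY_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

DEFAULT_CLASS_WEIGHTS = {
    "C>T@dipy": 0.50,
    "T>A@NTA": 0.23,
    "C>T": 0.08,
    "T>C": 0.07,
    "C>A": 0.05,
    "C>G": 0.04,
    "T>G": 0.03,
}


def _channel_sites(genome: Genome, spec: str):
    """Enumerate pyrimidine-frame candidate sites for a weight-spec channel.

    Returns (chrom array, pos array (1-based), py_strand array, ref, alt).
    Spec format ``REF>ALT`` optionally ``@ctx`` with ctx one of ``dipy``,
    a 3-letter pattern with N wildcards (e.g. ``NTA``), or an exact trinuc.
    """
    if "@" in spec:
        cls, ctx = spec.split("@", 1)
    else:
        cls, ctx = spec, None
    ref, alt = cls.split(">")
    if ref not in "CT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"bad pyrimidine-frame class {cls!r}")
    out_chrom, out_pos, out_strand = [], [], []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for chrom in genome.chrom_names:
        b = genome.bytes(chrom)
        L = len(b)
        for py_strand in STRANDS:
            plus_ref = ref if py_strand == "+" else comp[ref]
            hit = b == plus_ref.encode()
            hit[0] = hit[-1] = False  # need both flanking bases
            idx = np.nonzero(hit)[0]
            if ctx is not None and len(idx):
                five = b[idx - 1].astype("U1")
                three = b[idx + 1].astype("U1")
                if py_strand == "-":
                    # py-frame 5' neighbor is the complement of the plus-strand
                    # 3' neighbor and vice versa
                    five, three = (
                        np.array([comp[x] for x in three]),
                        np.array([comp[x] for x in five]),
                    )
                if ctx == "dipy":
                    keep = np.isin(five, ("C", "T")) | np.isin(three, ("C", "T"))
                else:
                    if len(ctx) != 3 or ctx[1] != ref:
                        raise ValueError(f"context pattern {ctx!r} must be 3 bases with ref center")
                    keep = np.ones(len(idx), dtype=bool)
                    if ctx[0] != "N":
                        keep &= five == ctx[0]
                    if ctx[2] != "N":
                        keep &= three == ctx[2]
                idx = idx[keep]
            out_chrom.append(np.full(len(idx), chrom, dtype=object))
            out_pos.append(idx + 1)
            out_strand.append(np.full(len(idx), py_strand, dtype=object))
    return (
        np.concatenate(out_chrom),
        np.concatenate(out_pos).astype(np.int64),
        np.concatenate(out_strand),
        ref,
        alt,
    )


def simulate_passaging_mutations(
    annotations: AnnotationSet,
    genome: Genome,
    n_isolates: int = 20,
    mean_per_isolate: float = 91.0,
    ts_fold: float = 4.0,
    class_weights: dict[str, float] | None = None,
    recurrent_fraction: float = 0.0,
    seed: int = 0,
    channel_ts_fold: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-isolate SNV records with transcribed-strand placement bias.

    Within gene bodies, a candidate site whose pyrimidine-frame base lies on
    the template strand receives placement weight ``ts_fold`` (vs 1 for the
    non-transcribed strand and intergenic sites), so downstream strand
    ratios recover ``ts_fold`` after trinucleotide-content normalization.
    ``channel_ts_fold`` overrides the fold for individual weight channels
    (e.g. leave the non-photoproduct T>A@NTA channel unbiased while
    photoproduct channels carry the full bias).  ``recurrent_fraction`` of
    the final records are exact cross-isolate duplicates, to exercise
    unique-mutation filtering.
    """
    if ts_fold <= 0:
        raise ValueError("ts_fold must be > 0")
    if not (0.0 <= recurrent_fraction < 1.0):
        raise ValueError("recurrent_fraction must be in [0, 1)")
    weights = dict(DEFAULT_CLASS_WEIGHTS if class_weights is None else class_weights)
    wsum = sum(weights.values())
    if wsum <= 0:
        raise ValueError("class weights must be normalizable")
    rng = np.random.default_rng(seed)

    # template-strand map per chromosome: '+'/'-'/'' outside genes
    tmpl = {c: np.zeros(L, dtype="U1") for c, L in genome.lengths.items()}
    for _, gene in annotations.genes.iterrows():
        lo, hi = gene_body(gene)
        tmpl[gene["chrom"]][lo - 1 : hi] = template_strand(gene["strand"])

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    folds = dict(channel_ts_fold or {})
    channels = []
    for spec, w in weights.items():
        chroms, poss, strands, ref, alt = _channel_sites(genome, spec)
        if len(poss) == 0:
            raise ValueError(f"no genomic sites match channel {spec!r}")
        fold = float(folds.get(spec, ts_fold))
        if fold <= 0:
            raise ValueError("channel ts folds must be > 0")
        site_w = np.ones(len(poss))
        in_body = np.zeros(len(poss), dtype=bool)
        for i in range(len(poss)):
            t = tmpl[chroms[i]][poss[i] - 1]
            if t:
                in_body[i] = True
                if t == strands[i]:
                    site_w[i] = fold
        # strand bias acts within gene bodies only: rescale body mass back to
        # its context-abundance share so the bias does not also shift the
        # channel's gene-body vs intergenic allocation
        body_mass = site_w[in_body].sum()
        if 0 < body_mass and in_body.any() and not in_body.all():
            site_w[in_body] *= in_body.sum() / body_mass
        site_w /= site_w.sum()
        channels.append((spec, w / wsum, chroms, poss, strands, ref, alt, site_w))

    counts = rng.poisson(mean_per_isolate, size=n_isolates)
    rows = []
    chan_p = np.array([c[1] for c in channels])
    for iso in range(n_isolates):
        picks = rng.choice(len(channels), size=counts[iso], p=chan_p)
        for ci in picks:
            _, _, chroms, poss, strands, ref, alt, site_w = channels[ci]
            j = rng.choice(len(poss), p=site_w)
            if strands[j] == "+":
                r, a = ref, alt
            else:
                r, a = comp[ref], comp[alt]
            rows.append((f"isolate_{iso + 1}", chroms[j], int(poss[j]), r, a))
    records = pd.DataFrame(rows, columns=["isolate", "chrom", "pos", "ref", "alt"])

    n_total = len(records)
    n_rec = int(round(recurrent_fraction * n_total))
    n_rec -= n_rec % 2  # duplicates come in cross-isolate pairs
    if n_rec and n_isolates >= 2:
        idx = rng.choice(n_total, size=n_rec, replace=False)
        for a_i, b_i in zip(idx[0::2], idx[1::2]):
            src = records.iloc[a_i]
            records.iloc[b_i, records.columns.get_indexer(["chrom", "pos", "ref", "alt"])] = [
                src["chrom"], src["pos"], src["ref"], src["alt"],
            ]
            if records.iloc[b_i]["isolate"] == src["isolate"]:
                others = [f"isolate_{k + 1}" for k in range(n_isolates)
                          if f"isolate_{k + 1}" != src["isolate"]]
                records.iloc[b_i, records.columns.get_loc("isolate")] = others[
                    int(rng.integers(len(others)))
                ]
    return records
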