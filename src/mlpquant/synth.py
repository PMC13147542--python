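"""Ground-truth-labeled synthetic fixtures for every analysis module.

Four generators, all deterministic given a seed, each with a sidecar truth
record that fully determines the expected downstream output:

* :func:`render_plate_pair` — pre/post-wash plate scans with planted
  per-position densities and adhesion ratios;
* :func:`simulate_plate_scan` — multi-point OD600 well scans with a tunable
  clump concentration;
* :func:`simulate_cross` — a biparental haploid cross with linked markers,
  haplotype structure, missing calls and one planted QTL;
* :func:`toy_genome` — a small annotated genome plus variants whose coding
  consequences are labeled at construction time by direct genome surgery.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.ndimage import gaussian_filter

from .flocculation import PlateScan, WellScan
from .imaging import EMPTY_TOKEN, GrayImage
from .varianteffects import GeneModel, GenotypeMatrix, Variant

__all__ = [
    "PlateSpec",
    "CrossSpec",
    "render_plate_pair",
    "simulate_plate_scan",
    "write_scan_csv",
    "simulate_cross",
    "toy_genome",
    "srb11_like_case",
    "write_fasta",
    "write_gff3",
    "write_variants",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# plate images


@dataclass(frozen=True)
class PlateSpec:
    """Geometry and planted truth for a rendered pre/post plate pair.

    Each of the 8 x 12 positions is pinned as a 7 x 7 arrangement of colony
    patches. ``densities`` and ``ratios`` are (8, 12) grids in [0, 1]; a
    density of 0 renders an empty square. Intensities are on the 0-255
    scale; ``noise_sd`` is the Gaussian pixel-noise standard deviation in
    those units. A small dark fiducial in the margin (emulating the plate
    rim that is dark in every scan) anchors per-image max normalization so
    pre and post images share a density scale.
    """

    densities: np.ndarray
    ratios: np.ndarray
    n_rows: int = 8
    n_cols: int = 12
    pitch: int = 36
    margin: int = 20
    patch_grid: int = 7
    patch_px: int = 4
    background_inv: float = 10.0
    amplitude: float = 240.0
    noise_sd: float = 3.0
    blur_sigma: float = 0.7
    patch_jitter_sd: float = 0.03
    shift: tuple[int, int] = (0, 0)
    seed: int = 0
    white_level: float = 255.0

    def __post_init__(self) -> None:
        dens = np.asarray(self.densities, dtype=float)
        rat = np.asarray(self.ratios, dtype=float)
        if dens.shape != (self.n_rows, self.n_cols) or rat.shape != dens.shape:
            raise ValueError("densities and ratios must be (n_rows, n_cols)")
        if dens.min() < 0 or dens.max() > 1 or rat.min() < 0 or rat.max() > 1:
            raise ValueError("densities and ratios must lie in [0, 1]")
        if self.background_inv + self.amplitude > self.white_level:
            raise ValueError("background + amplitude exceeds the white level")
        object.__setattr__(self, "densities", dens)
        object.__setattr__(self, "ratios", rat)

    @property
    def canvas(self) -> tuple[int, int]:
        return (
            2 * self.margin + self.n_rows * self.pitch,
            2 * self.margin + self.n_cols * self.pitch,
        )


def _colony_layer(spec: PlateSpec, values: np.ndarray, jitter: np.ndarray) -> np.ndarray:
    """Inverse-intensity contribution of the colonies (pre-noise, pre-blur)."""
    h, w = spec.canvas
    layer = np.zeros((h, w))
    dy, dx = spec.shift
    side = spec.patch_grid * spec.patch_px
    inset = (spec.pitch - side) // 2
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            if values[r, c] <= 0:
                continue
            top = spec.margin + r * spec.pitch + inset + dy
            left = spec.margin + c * spec.pitch + inset + dx
            for pr in range(spec.patch_grid):
                for pc in range(spec.patch_grid):
                    amp = values[r, c] * spec.amplitude * jitter[r, c, pr, pc]
                    y0 = top + pr * spec.patch_px
                    x0 = left + pc * spec.patch_px
                    layer[y0 : y0 + spec.patch_px, x0 : x0 + spec.patch_px] = amp
    return layer


def render_plate_pair(
    spec: PlateSpec,
) -> tuple[GrayImage, GrayImage, pd.DataFrame]:
    """Render a pre/post-wash scan pair with its sidecar truth table.

    The prewash image draws each position's 49 patches at inverse intensity
    proportional to the planted density over a uniform background; the
    postwash image scales each position by its planted ratio (with identical
    per-patch jitter, so the planted ratio is exact pre-noise). The truth
    table records, per position, the planted density and ratio and the
    expected measured (background-corrected, normalized) prewash density.
    """
    h, w = spec.canvas
    side = spec.patch_grid * spec.patch_px
    if side > spec.pitch:
        raise ValueError("patch arrangement larger than the box pitch")
    if spec.margin < 12:
        raise ValueError("canvas margin too small for the fiducial")
    rng = np.random.default_rng(spec.seed)
    jitter = 1.0 + spec.patch_jitter_sd * rng.standard_normal(
        (spec.n_rows, spec.n_cols, spec.patch_grid, spec.patch_grid)
    )
    jitter = np.clip(jitter, 0.5, 1.5)

    headroom = spec.white_level - spec.background_inv
    pre_layer = np.minimum(_colony_layer(spec, spec.densities, jitter), headroom)
    post_layer = np.minimum(
        _colony_layer(spec, spec.densities * spec.ratios, jitter), headroom
    )

    dy, dx = spec.shift
    fy, fx = 8 + dy, 8 + dx  # fiducial moves rigidly with the plate
    if fy < 0 or fx < 0 or fy + 6 > h or fx + 6 > w:
        raise ValueError("shift moves the fiducial outside the canvas")
    images = []
    for layer in (pre_layer, post_layer):
        inv = layer + spec.background_inv
        # dark fiducial in the margin: pins the per-image darkest pixel
        inv[fy : fy + 6, fx : fx + 6] = spec.white_level
        inv = gaussian_filter(inv, sigma=spec.blur_sigma)
        pixels = spec.white_level - inv + spec.noise_sd * rng.standard_normal((h, w))
        images.append(
            GrayImage(
                pixels=np.clip(pixels, 0, spec.white_level),
                white_level=spec.white_level,
            )
        )

    # expected measured prewash density: in-box mean of the rendered inverse-
    # intensity layer over the white level (the fiducial pins per-image max
    # normalization at white_level, and background subtraction removes the
    # uniform background)
    expected_pre = np.empty((spec.n_rows, spec.n_cols))
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            top = spec.margin + r * spec.pitch + dy
            left = spec.margin + c * spec.pitch + dx
            box = pre_layer[top : top + spec.pitch, left : left + spec.pitch]
            expected_pre[r, c] = box.mean() / spec.white_level
    rows, cols = np.meshgrid(
        np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij"
    )
    truth = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "density": spec.densities.ravel(),
            "ratio": spec.ratios.ravel(),
            "expected_pre": expected_pre.ravel(),
            "is_empty": (spec.densities.ravel() == 0),
        }
    )
    return images[0], images[1], truth


def default_plate_spec(
    seed: int = 0,
    noise_sd: float = 3.0,
    shift: tuple[int, int] = (0, 0),
    empty_positions: tuple[tuple[int, int], ...] = ((7, 11),),
) -> PlateSpec:
    """A filled study plate: densities U(0.3, 1), ratios on a 0..1 grid."""
    rng = np.random.default_rng(seed)
    densities = rng.uniform(0.3, 1.0, size=(8, 12))
    ratios = rng.choice(np.round(np.linspace(0.0, 1.0, 11), 1), size=(8, 12))
    for r, c in empty_positions:
        densities[r, c] = 0.0
        ratios[r, c] = 0.0
    return PlateSpec(
        densities=densities, ratios=ratios, noise_sd=noise_sd, shift=shift, seed=seed
    )


# ---------------------------------------------------------------------------
# plate-reader scans


def _well_ids(n_rows: int = 8, n_cols: int = 12) -> list[str]:
    return [
        f"{r}{c}" for r in string.ascii_uppercase[:n_rows] for c in range(1, n_cols + 1)
    ]


def simulate_plate_scan(
    clump_parameter: float | dict[str, float],
    n: int = 15,
    baseline: float = 0.5,
    background: float = 0.05,
    noise_sd: float = 0.01,
    n_clumps: int = 3,
    control_well: str = "H12",
    seed: int | None = None,
) -> tuple[PlateScan, pd.DataFrame]:
    """Simulate multi-point OD600 scans of a 96-well plate with flocs.

    Every non-control well holds ``baseline`` OD of dispersed cells plus
    ``n_clumps`` clumps placed uniformly on the n x n grid; each clump adds
    a spike of OD mass proportional to ``clump_parameter`` (scalar, or per
    well id), so spatial heterogeneity — and hence the CV — grows with the
    parameter. The control well contains medium only. Truth records each
    well's baseline and clump parameter.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    wells: dict[str, WellScan] = {}
    truth_rows = []
    for wid in _well_ids():
        is_control = wid == control_well
        base = 0.0 if is_control else baseline
        c = 0.0
        if not is_control:
            c = clump_parameter if np.isscalar(clump_parameter) else clump_parameter.get(wid, 0.0)
        grid = background + base + noise_sd * rng.standard_normal((n, n))
        if c > 0:
            for _ in range(n_clumps):
                i, j = rng.integers(0, n, size=2)
                grid[i, j] += c * baseline * rng.uniform(0.8, 1.2)
        wells[wid] = WellScan(wid, np.clip(grid, 0.0, None))
        truth_rows.append((wid, base, float(c)))
    plate = PlateScan(wells=wells, control_well=control_well)
    truth = pd.DataFrame(truth_rows, columns=["well", "baseline", "clump_parameter"])
    return plate, truth


def write_scan_csv(plate: PlateScan, path: str | Path) -> None:
    """Write a plate scan in the documented CSV dialect (one row per well)."""
    with Path(path).open("w") as fh:
        for wid, well in plate.wells.items():
            flat = ",".join(f"{v:.6g}" for v in well.readings.ravel())
            fh.write(f"{wid},{flat}\n")


def simulate_screen(
    n_strains: int = 3600,
    positive_rate: float = 0.05,
    n_replicates: int = 6,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a deletion-screen replicate table with planted adhesives.

    A fixed fraction of strains are planted adhesive (mean ratio ~0.3);
    the rest carry only residual wash ratios (~0.03), well separated.
    Replicate pre-wash densities vary around 0.45 with occasional
    low-growth replicates. Returns the long replicate table (strain,
    pre_density, post_density, ratio) and the per-strain truth.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_strains * positive_rate))
    adhesive = np.zeros(n_strains, dtype=bool)
    adhesive[rng.choice(n_strains, size=n_pos, replace=False)] = True
    strain_ratio = np.where(
        adhesive,
        rng.normal(0.30, 0.05, n_strains),
        rng.normal(0.03, 0.012, n_strains),
    ).clip(0.0, 1.0)
    rows = []
    for i in range(n_strains):
        for _ in range(n_replicates):
            pre = max(0.0, rng.normal(0.45, 0.10))
            if rng.random() < 0.02:  # occasional failed pinning
                pre = rng.uniform(0.0, 0.08)
            ratio = max(0.0, strain_ratio[i] + rng.normal(0.0, 0.01))
            rows.append((f"d{i:04d}", pre, pre * ratio, ratio))
    table = pd.DataFrame(
        rows, columns=["strain", "pre_density", "post_density", "ratio"]
    )
    truth = pd.DataFrame(
        {
            "strain": [f"d{i:04d}" for i in range(n_strains)],
            "adhesive": adhesive,
            "ratio": strain_ratio,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# segregant cross


@dataclass(frozen=True)
class CrossSpec:
    """A biparental haploid cross with dense, tightly linked markers.

    Markers emulate dense SNP sets: the per-interval recombination
    probability is small, so markers collapse into a handful of haplotype
    blocks across the library (each strain's chromosome is a two-state
    Markov chain over the marker sequence). One marker carries the QTL:
    phenotype = effect x [allele == P2] + N(0, noise_sd), in phenotype-sd
    units. ``missing_rate`` masks calls at random.
    """

    n_strains: int = 100
    markers_per_chromosome: tuple[int, ...] = (80, 70, 50)
    chromosome_names: tuple[str, ...] = ("I", "II", "III")
    marker_spacing: int = 2500
    recombination: float = 5e-5
    qtl_chromosome: str = "II"
    qtl_marker_index: int = 35
    effect: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.recombination <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.markers_per_chromosome) != len(self.chromosome_names):
            raise ValueError("one marker count per chromosome required")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")


def simulate_cross(
    spec: CrossSpec,
) -> tuple[GenotypeMatrix, pd.Series, dict]:
    """Simulate the segregant library; truth records the planted QTL marker."""
    rng = np.random.default_rng(spec.seed)
    strains = [f"seg{i + 1:03d}" for i in range(spec.n_strains)]
    columns: list[str] = []
    marker_rows = []
    chrom_alleles = []
    for chrom, n_markers in zip(spec.chromosome_names, spec.markers_per_chromosome):
        start = rng.integers(0, 2, size=(spec.n_strains, 1))
        switches = rng.random((spec.n_strains, n_markers - 1)) < spec.recombination
        # start value + number of haplotype switches so far, mod 2
        alleles = (start + np.concatenate(
            [np.zeros((spec.n_strains, 1), dtype=int), switches.cumsum(axis=1)], axis=1
        )) % 2
        chrom_alleles.append(alleles)
        for k in range(n_markers):
            pos = (k + 1) * spec.marker_spacing
            columns.append(f"{chrom}:{pos}")
            marker_rows.append((chrom, pos))
    genotype = np.concatenate(chrom_alleles, axis=1)

    qtl_col = (
        sum(
            n
            for ch, n in zip(spec.chromosome_names, spec.markers_per_chromosome)
            if _chrom_before(ch, spec.qtl_chromosome, spec.chromosome_names)
        )
        + spec.qtl_marker_index
    )
    qtl_alleles = genotype[:, qtl_col]
    phenotype = spec.effect * qtl_alleles + spec.noise_sd * rng.standard_normal(
        spec.n_strains
    )

    labels = np.where(genotype == 0, "P1", "P2").astype(object)
    mask = rng.random(labels.shape) < spec.missing_rate
    labels[mask] = None
    data = pd.DataFrame(labels, index=strains, columns=columns)
    markers = pd.DataFrame(
        marker_rows, columns=["chromosome", "pos"], index=columns
    )
    truth = {
        "qtl_marker": columns[qtl_col],
        "qtl_chromosome": spec.qtl_chromosome,
        "qtl_pos": int(markers.iloc[qtl_col]["pos"]),
        "qtl_alleles": qtl_alleles.copy(),
        "recombination_breakpoints": int(
            sum(
                int(np.any(np.diff(a, axis=1).astype(bool)[:, k]))
                for a in chrom_alleles
                for k in range(a.shape[1] - 1)
            )
        ),
    }
    return (
        GenotypeMatrix(data=data, markers=markers),
        pd.Series(phenotype, index=strains, name="phenotype"),
        truth,
    )


def _chrom_before(ch: str, target: str, order: tuple[str, ...]) -> bool:
    return order.index(ch) < order.index(target)


# ---------------------------------------------------------------------------
# toy genome with labeled variant consequences


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(str(rng.choice(sorted(_STOPS))))
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


@dataclass
class _ToyGene:
    model: GeneModel
    cds: str  # spliced CDS in transcription order


def _place_gene(
    rng: np.random.Generator,
    chrom_name: str,
    offset: int,
    gene_id: str,
    strand: str,
    two_exon: bool,
) -> tuple[str, _ToyGene]:
    """Build one gene's genomic locus; returns (locus sequence, gene)."""
    n_codons = int(rng.integers(60, 200))
    cds = _random_cds(rng, n_codons)
    if two_exon:
        cut = int(rng.integers(30, len(cds) - 30))
        intron = "GT" + _random_dna(rng, int(rng.integers(40, 80))) + "AG"
        tx_locus = cds[:cut] + intron + cds[cut:]
        exon1 = (1, cut)  # transcript-order intervals within the locus
        exon2 = (cut + len(intron) + 1, len(tx_locus))
    else:
        tx_locus = cds
        exon1 = (1, len(cds))
        exon2 = None
    if strand == "+":
        locus = tx_locus
        intervals = [exon1] if exon2 is None else [exon1, exon2]
    else:
        locus = str(Seq(tx_locus).reverse_complement())
        L = len(tx_locus)
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        intervals = [flip(exon1)] if exon2 is None else [flip(exon2), flip(exon1)]
    genomic = tuple(sorted((offset + a, offset + b) for a, b in intervals))
    model = GeneModel(
        gene_id=gene_id,
        chromosome=chrom_name,
        strand=strand,
        cds_intervals=genomic,
    )
    return locus, _ToyGene(model=model, cds=cds)


def _true_consequence(
    genome: dict[str, str], gene: GeneModel, variant: Variant
) -> tuple[str, int, int, bool]:
    """Construction-time label by direct genome surgery.

    Applies the edit to the chromosome string, shifts the gene's CDS
    intervals past the edit, re-splices and translates. Independent of the
    CDS-space editing used by the consequence caller.
    """
    chrom = genome[variant.chromosome]
    pos0 = variant.pos - 1
    new_chrom = chrom[:pos0] + variant.alt + chrom[pos0 + len(variant.ref) :]
    delta = len(variant.alt) - len(variant.ref)
    new_intervals = []
    for a, b in gene.cds_intervals:
        if delta == 0:
            new_intervals.append((a, b))  # substitutions never move coordinates
        elif a <= variant.pos <= b:
            # anchored indel whose changed span lies inside this exon
            new_intervals.append((a, b + delta))
        elif a > variant.pos:
            new_intervals.append((a + delta, b + delta))
        else:
            new_intervals.append((a, b))
    spliced = "".join(new_chrom[a - 1 : b] for a, b in new_intervals)
    if gene.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    ref_spliced = "".join(chrom[a - 1 : b] for a, b in gene.cds_intervals)
    if gene.strand == "-":
        ref_spliced = str(Seq(ref_spliced).reverse_complement())

    def translate(cds: str) -> str:
        usable = len(cds) - len(cds) % 3
        protein = str(Seq(cds[:usable]).translate())
        stop = protein.find("*")
        return protein if stop < 0 else protein[:stop]

    ref_protein = translate(ref_spliced)
    alt_protein = translate(spliced)
    in_cds = any(
        a <= variant.pos + k <= b
        for a, b in gene.cds_intervals
        for k in range(max(1, len(variant.ref)))
    )
    if delta != 0:
        category = "frameshift" if delta % 3 != 0 else "inframe_indel"
    elif alt_protein == ref_protein:
        category = "synonymous"
    elif len(alt_protein) < len(ref_protein) and ref_protein.startswith(alt_protein):
        category = "nonsense"
    else:
        category = "missense"
    return (
        category,
        len(ref_protein),
        len(alt_protein),
        len(alt_protein) < len(ref_protein),
    )


def toy_genome(
    seed: int = 0,
    n_genes: int = 12,
    n_variants: int = 220,
) -> tuple[dict[str, str], list[GeneModel], list[Variant], pd.DataFrame]:
    """A small annotated genome plus variants labeled at construction time.

    Genes sit on both strands, single- and two-exon, separated by random
    intergenic spacers, across 3 chromosomes. Variants are a mix of coding
    SNPs, small indels (1-2 bp frameshifting, 3 bp in-frame) placed strictly
    inside exons, and intergenic variants; each is labeled by direct genome
    surgery and translation (see :func:`_true_consequence`). The truth table
    carries chrom, pos, ref, alt, gene, category, protein lengths.
    """
    rng = np.random.default_rng(seed)
    chrom_names = ("chrI", "chrII", "chrIII")
    genome: dict[str, str] = {}
    genes: list[_ToyGene] = []
    gi = 0
    for chrom in chrom_names:
        parts = [_random_dna(rng, int(rng.integers(150, 300)))]
        offset = len(parts[0])
        for _ in range(n_genes // len(chrom_names)):
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            two_exon = rng.random() < 0.5
            locus, gene = _place_gene(
                rng, chrom, offset, f"gene{gi:02d}", strand, two_exon
            )
            parts.append(locus)
            genes.append(gene)
            spacer = _random_dna(rng, int(rng.integers(150, 300)))
            parts.append(spacer)
            offset += len(locus) + len(spacer)
        genome[chrom] = "".join(parts)

    models = [g.model for g in genes]
    variants: list[Variant] = []
    rows = []
    kinds = ["snp"] * 3 + ["del1", "ins1", "del3"]
    attempts = 0
    while len(variants) < n_variants and attempts < n_variants * 50:
        attempts += 1
        if rng.random() < 0.8:
            gene = genes[int(rng.integers(len(genes)))]
            chrom = gene.model.chromosome
            exon = gene.model.cds_intervals[int(rng.integers(len(gene.model.cds_intervals)))]
            kind = kinds[int(rng.integers(len(kinds)))]
            a, b = exon
            if kind == "snp":
                pos = int(rng.integers(a, b + 1))
                ref = genome[chrom][pos - 1]
                alt = str(rng.choice([x for x in _BASES if x != ref]))
            elif kind in ("del1", "del3"):
                k = 1 if kind == "del1" else 3
                if b - a < k + 2:
                    continue
                pos = int(rng.integers(a, b - k))  # anchor; deleted span in exon
                ref = genome[chrom][pos - 1 : pos - 1 + k + 1]
                alt = ref[0]
            else:  # 1-bp insertion, anchor and next base inside the exon
                pos = int(rng.integers(a, b))
                ref = genome[chrom][pos - 1]
                alt = ref + str(rng.choice(list(_BASES)))
            gene_model = gene.model
        else:
            chrom = str(rng.choice(chrom_names))
            pos = int(rng.integers(1, 120))  # leading intergenic spacer
            ref = genome[chrom][pos - 1]
            alt = str(rng.choice([x for x in _BASES if x != ref]))
            gene_model = None
        if any(v.chromosome == chrom and v.pos == pos for v in variants):
            continue
        variant = Variant(chromosome=chrom, pos=pos, ref=ref, alt=alt)
        if gene_model is None:
            category, lref, lalt, prem = "non_coding", 0, 0, False
            gene_id = ""
        else:
            category, lref, lalt, prem = _true_consequence(
                genome, gene_model, variant
            )
            gene_id = gene_model.gene_id
        variants.append(variant)
        rows.append(
            (chrom, pos, ref, alt, gene_id, category, lref, lalt, prem)
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene",
            "category",
            "protein_length_ref",
            "protein_length_alt",
            "premature_stop",
        ],
    )
    return genome, models, variants, truth


def srb11_like_case(flank: int = 150, seed: int = 11) -> tuple[dict[str, str], GeneModel, Variant]:
    """Synthetic stand-in for the srb11 frameshift worked example.

    Reconstructs the geometry of the mapped causal variant — a cyclin-C-like
    gene whose reference protein is 228 aa and where an anchored TA>T 1-bp
    deletion shifts the frame so the truncated product is exactly 77 aa —
    on a constructed sequence. This is NOT the real genomic sequence (it is
    built offline); only the coordinate arithmetic and translation geometry
    match the real case.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    while len(codons) < 76:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAC")  # codon 76 (0-based): supplies the TA anchor
    codons.append("ATA")  # codon 77
    codons.append("AAA")  # codon 78
    while len(codons) < 228:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    cds = "".join(codons)
    # shifted frame after deleting the A of codon 76: TC|A -> "TC?" then stop
    assert cds[228:231] == "TAC" and cds[231:234] == "ATA"
    cds = cds[:232] + "TAA" + cds[235:]  # plant the shifted-frame stop
    # the reference frame stays open: codons 77/78 read ATA / AAA
    assert cds[231:234] == "ATA" and cds[234:237] == "AAA"

    chrom = _random_dna(rng, flank) + cds + _random_dna(rng, flank)
    cds_start = flank + 1
    gene = GeneModel(
        gene_id="cycC_synth",
        chromosome="II_synth",
        strand="+",
        cds_intervals=((cds_start, cds_start + len(cds) - 1),),
    )
    # anchored deletion of the A at CDS position 230 (1-based): ref TA, alt T
    pos = cds_start + 228
    variant = Variant(chromosome="II_synth", pos=pos, ref="TA", alt="T")
    genome = {"II_synth": chrom}
    assert genome["II_synth"][pos - 1 : pos + 1] == "TA"
    return genome, gene, variant


# ---------------------------------------------------------------------------
# writers (plain-text round-trip formats)


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 gene/mRNA/CDS features."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            lo, hi = gene.span
            fh.write(
                f"{gene.chromosome}\tmlpquant\tgene\t{lo}\t{hi}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            mrna = f"{gene.gene_id}.1"
            fh.write(
                f"{gene.chromosome}\tmlpquant\tmRNA\t{lo}\t{hi}\t.\t"
                f"{gene.strand}\t.\tID={mrna};Parent={gene.gene_id}\n"
            )
            tx_order = (
                gene.cds_intervals
                if gene.strand == "+"
                else tuple(reversed(gene.cds_intervals))
            )
            phases, cum = {}, 0
            for a, b in tx_order:
                phases[(a, b)] = (3 - cum % 3) % 3
                cum += b - a + 1
            for i, (a, b) in enumerate(gene.cds_intervals):
                fh.write(
                    f"{gene.chromosome}\tmlpquant\tCDS\t{a}\t{b}\t.\t"
                    f"{gene.strand}\t{phases[(a, b)]}\tID={mrna}.cds{i};"
                    f"Parent={mrna}\n"
                )


def write_variants(variants: list[Variant], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(v.chromosome, v.pos, v.ref, v.alt) for v in variants],
        columns=["CHROM", "POS", "REF", "ALT"],
    )
    frame.to_csv(path, sep="\t", index=False)
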