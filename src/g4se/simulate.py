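"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and a seed. A single
global seed expands into per-component child streams through
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed component
key (genome/peaks 0, sequences 1, binding traces 2, droplet images 3, Cq
tables 4), so adding or re-running one generator never perturbs the others.

The genomic generator emulates the structure of SE/peak catalogs:

* non-overlapping superenhancers per cell line, a configurable fraction of
  the target-cell SEs shared with the other cell line;
* CAGE (enhancer RNA) peaks inside a configurable fraction of target SEs;
* folded-G4 (BG4) and potential-G4 (G4-seq) peaks whose *density* inside SE
  bases is ``enrichment_rho`` times the outside density (rho = 1 is the
  null), placed by sampling the peak midpoint;
* BRD4 anchor peaks inside SEs, with nucleosome-free DHS (and folded G4)
  peaks offset 0-100 bp from the anchors and H3K27ac peaks clustered in the
  flanks at 200-500 bp — the colocalization geometry of active SEs.

The planted parameters are returned in a truth record sufficient to compute
every downstream expected value without re-simulation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .binding import (
    FrapParams,
    HillParams,
    KineticParams,
    frap_curve,
    hill_curve,
    spr_trace,
    two_site_free_fraction,
)
from .genome import GenomeLayout, Interval, IntervalSet
from .intervals import merge

__all__ = [
    "SE_G4_MOTIF",
    "SimulationConfig",
    "PeakBundle",
    "component_rng",
    "simulate_genome_and_peaks",
    "place_peaks",
    "simulate_sequences",
    "simulate_binding_trace",
    "simulate_droplet_image",
    "simulate_cq_table",
]

#: the SE-enriched G4 motif A(G3A)4: guanine triplets with single-A loops
SE_G4_MOTIF = "AGGGAGGGAGGGAGGGA"

_COMPONENT_KEYS = {"peaks": 0, "sequences": 1, "traces": 2, "images": 3, "cq": 4}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Child generator for one simulation component (documented scheme)."""
    key = _COMPONENT_KEYS[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Study-condition defaults for the genomic generator.

    The genome is 4 x 50 Mb; 200 target-cell SEs of 10-30 kb (about 2% of
    the genome, so a planted density ratio rho translates into a nearly
    equal overlap fold enrichment); 2000 peaks of 150-400 bp per mark; half
    of the target SEs CAGE-positive; H3K27ac offset 200-500 bp from BRD4
    anchors and DHS/BG4 offsets within 100 bp.
    """

    seed: int = 0
    chrom_lengths: tuple = (50_000_000, 50_000_000, 50_000_000, 50_000_000)
    target_cell: str = "K562"
    other_cell: str = "HEK293"
    n_se: int = 200
    n_se_other: int = 200
    shared_se_fraction: float = 0.3
    se_length_range: tuple = (10_000, 30_000)
    n_peaks: int = 2000
    peak_length_range: tuple = (150, 400)
    enrichment_rho: float = 3.0
    cage_fraction: float = 0.5
    cage_peak_length: int = 100
    n_anchors: int = 300
    anchor_flank_offset: tuple = (200, 500)  # H3K27ac
    anchor_proximal_offset: tuple = (0, 100)  # DHS and anchored BG4
    trace_noise_sd: float = 0.02
    image_noise_sd: float = 300.0

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))
        return GenomeLayout(names, tuple(self.chrom_lengths))


@dataclass
class PeakBundle:
    """Output of :func:`simulate_genome_and_peaks`."""

    layout: GenomeLayout
    se_catalogs: dict
    cage: IntervalSet
    peaks: dict  # mark -> IntervalSet (BG4, G4seq, DHS, BRD4, H3K27ac)
    truth: dict


# ------------------------------------------------------------ interval tools


def _place_nonoverlapping(
    n: int,
    length_range: tuple,
    layout: GenomeLayout,
    rng: np.random.Generator,
    avoid: IntervalSet | None = None,
    max_tries: int = 200,
) -> list[Interval]:
    chrom_lengths = np.asarray(layout.chrom_lengths, dtype=np.int64)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    if avoid is not None:
        for iv in avoid:
            placed[iv.chrom].append((iv.start, iv.end))
    out: list[Interval] = []
    for _ in range(n):
        ok = False
        for _try in range(max_tries):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            weights = np.maximum(chrom_lengths - L + 1, 0)
            total = int(weights.sum())
            if total == 0:
                break
            u = rng.random() * total
            ci = int(np.searchsorted(np.cumsum(weights), u, side="right"))
            start = int(rng.integers(0, weights[ci]))
            chrom = layout.chrom_names[ci]
            end = start + L
            if all(e <= start or s >= end for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                out.append(Interval(chrom, start, end))
                ok = True
                break
        if not ok:
            raise ValueError(
                "could not place non-overlapping intervals; use a larger genome "
                "layout or fewer/shorter intervals"
            )
    return out


def place_peaks(
    n: int,
    length_range: tuple,
    regions: IntervalSet,
    rho: float,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> IntervalSet:
    """Peaks whose midpoint density inside ``regions`` is rho x the outside
    density. rho = 1 is uniform placement (the null); rho = 0 excludes the
    regions entirely."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    mregions = merge(regions)
    ms, me = mregions.global_coords()
    inside_bases = int((me - ms).sum())
    G = layout.total_length
    outside_bases = G - inside_bases
    p_in = rho * inside_bases / (rho * inside_bases + outside_bases)
    offs = layout.offsets()
    chrom_names = layout.chrom_names
    chrom_offsets = np.array([offs[c] for c in chrom_names], dtype=np.int64)
    chrom_lengths = np.asarray(layout.chrom_lengths, dtype=np.int64)

    # cumulative base counts for uniform sampling inside region bases
    region_cum = np.concatenate(([0], np.cumsum(me - ms)))
    out: list[Interval] = []
    for _ in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        if rng.random() < p_in:
            u = int(rng.integers(0, inside_bases))
            j = int(np.searchsorted(region_cum, u, side="right")) - 1
            mid = int(ms[j] + (u - region_cum[j]))
        else:
            while True:
                mid = int(rng.integers(0, G))
                j = int(np.searchsorted(ms, mid, side="right")) - 1
                if j < 0 or me[j] <= mid:
                    break
        ci = int(np.searchsorted(chrom_offsets, mid, side="right")) - 1
        local_mid = mid - int(chrom_offsets[ci])
        start = max(0, min(local_mid - L // 2, int(chrom_lengths[ci]) - L))
        out.append(Interval(chrom_names[ci], start, start + L))
    return IntervalSet(out, layout)


def _offset_peaks(
    anchors: list[Interval],
    offset_range: tuple,
    length: int,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> IntervalSet:
    """One peak per anchor, its center displaced by a signed offset drawn
    uniformly from +/-[offset_range]."""
    out: list[Interval] = []
    for iv in anchors:
        off = int(rng.integers(offset_range[0], offset_range[1] + 1))
        if rng.random() < 0.5:
            off = -off
        center = iv.midpoint + off
        start = max(0, min(center - length // 2, layout.length(iv.chrom) - length))
        out.append(Interval(iv.chrom, start, start + length))
    return IntervalSet(out, layout)


def simulate_genome_and_peaks(config: SimulationConfig) -> PeakBundle:
    """Generate SE catalogs, CAGE, and all peak tracks with planted structure."""
    rng = component_rng(config.seed, "peaks")
    layout = config.layout()

    target_ses = _place_nonoverlapping(
        config.n_se, config.se_length_range, layout, rng
    )
    n_shared = int(round(config.shared_se_fraction * config.n_se_other))
    n_shared = min(n_shared, len(target_ses))
    shared = list(rng.choice(len(target_ses), size=n_shared, replace=False))
    target_set = IntervalSet(target_ses, layout)
    other_unique = _place_nonoverlapping(
        config.n_se_other - n_shared,
        config.se_length_range,
        layout,
        rng,
        avoid=target_set,
    )
    other_set = IntervalSet(
        [target_ses[i] for i in shared] + other_unique, layout
    )

    # CAGE peaks inside a fraction of target SEs
    n_cage = int(round(config.cage_fraction * len(target_ses)))
    cage_idx = sorted(rng.choice(len(target_ses), size=n_cage, replace=False))
    cage_ivs = []
    for i in cage_idx:
        se = target_ses[i]
        lo = se.start
        hi = max(lo + 1, se.end - config.cage_peak_length)
        start = int(rng.integers(lo, hi))
        end = min(start + config.cage_peak_length, se.end)
        cage_ivs.append(Interval(se.chrom, start, end))
    cage = IntervalSet(cage_ivs, layout)

    bg4 = place_peaks(
        config.n_peaks, config.peak_length_range, target_set,
        config.enrichment_rho, layout, rng,
    )
    g4seq = place_peaks(
        config.n_peaks, config.peak_length_range, target_set,
        config.enrichment_rho, layout, rng,
    )

    # BRD4 anchors: midpoints strictly inside SEs (rho -> infinity limit)
    anchor_ivs: list[Interval] = []
    ms, me = merge(target_set).global_coords()
    region_cum = np.concatenate(([0], np.cumsum(me - ms)))
    inside_bases = int(region_cum[-1])
    offs = layout.offsets()
    chrom_offsets = np.array(
        [offs[c] for c in layout.chrom_names], dtype=np.int64
    )
    for _ in range(config.n_anchors):
        L = int(rng.integers(*config.peak_length_range))
        u = int(rng.integers(0, inside_bases))
        j = int(np.searchsorted(region_cum, u, side="right")) - 1
        mid = int(ms[j] + (u - region_cum[j]))
        ci = int(np.searchsorted(chrom_offsets, mid, side="right")) - 1
        local_mid = mid - int(chrom_offsets[ci])
        chrom = layout.chrom_names[ci]
        start = max(0, min(local_mid - L // 2, layout.length(chrom) - L))
        anchor_ivs.append(Interval(chrom, start, start + L))
    brd4 = IntervalSet(anchor_ivs, layout)
    peak_len = int(np.mean(config.peak_length_range))
    h3k27ac = _offset_peaks(
        anchor_ivs, config.anchor_flank_offset, peak_len, layout, rng
    )
    dhs = _offset_peaks(
        anchor_ivs, config.anchor_proximal_offset, peak_len, layout, rng
    )

    truth = {
        "config": asdict(config),
        "n_target_se": len(target_ses),
        "shared_indices": [int(i) for i in shared],
        "cage_positive_indices": [int(i) for i in cage_idx],
        "enrichment_rho": config.enrichment_rho,
        "se_base_fraction": merge(target_set).total_length() / layout.total_length,
    }
    return PeakBundle(
        layout=layout,
        se_catalogs={config.target_cell: target_set, config.other_cell: other_set},
        cage=cage,
        peaks={"BG4": bg4, "G4seq": g4seq, "DHS": dhs, "BRD4": brd4,
               "H3K27ac": h3k27ac},
        truth=truth,
    )


# ---------------------------------------------------------------- sequences


def simulate_sequences(
    seed: int | np.random.Generator,
    n_sequences: int = 18,
    length: int = 2000,
    gc_content: float = 0.4,
    motif: str = SE_G4_MOTIF,
    n_insertions: int = 1,
) -> tuple[dict, dict]:
    """Random-background sequences with the motif planted at known positions.

    Returns (name -> sequence, name -> list of 0-based insertion starts);
    planted copies are recoverable by exact string search.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else component_rng(seed, "sequences")
    )
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    alphabet = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    positions: dict[str, list[int]] = {}
    m = len(motif)
    for i in range(n_sequences):
        name = f"seq{i + 1}"
        bases = rng.choice(alphabet, size=length, p=p)
        pos_list: list[int] = []
        tries = 0
        while len(pos_list) < n_insertions and tries < 1000:
            tries += 1
            start = int(rng.integers(0, length - m + 1))
            if all(abs(start - q) >= m for q in pos_list):
                pos_list.append(start)
        for start in pos_list:
            bases[start : start + m] = list(motif)
        seqs[name] = "".join(bases)
        positions[name] = sorted(pos_list)
    return seqs, positions


# ------------------------------------------------------------ binding traces


def simulate_binding_trace(
    model: str,
    params: dict,
    design: dict | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Forward-simulate one binding/kinetic/recovery experiment.

    model: "two_site" | "hill" | "spr" | "frap". At noise_sd = 0 the trace
    equals the model prediction exactly. Default designs mirror the assay
    regimes: an NMR-style titration of ~12 uM folded G4 observed through 5
    imino signals against up to 8.4 uM protein; an MST 2-fold dilution
    series; SPR sensograms at 1-200 uM analyte; a 10-minute recovery curve
    sampled every 10 s.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else component_rng(seed, "traces")
    )
    design = dict(design or {})
    if model == "two_site":
        G = float(design.get("G_total", 12.0))
        B = np.asarray(design.get("B_total", np.linspace(0.0, 8.4, 7)), dtype=float)
        n_signals = int(design.get("n_signals", 5))
        kd = float(params["K_d"])
        rows = []
        for b in B:
            f = two_site_free_fraction(G, b, kd) if b > 0 else 1.0
            for s in range(n_signals):
                rows.append((G, b, s + 1, f))
        df = pd.DataFrame(rows, columns=["G_total", "B_total", "signal", "intensity"])
        clean = df["intensity"].to_numpy().copy()
        df["intensity"] = clean + noise_sd * rng.standard_normal(len(df))
    elif model == "hill":
        L = np.asarray(
            design.get("concentrations", 200.0 / 2 ** np.arange(12)[::-1]),
            dtype=float,
        )
        hp = HillParams(**params)
        clean = hill_curve(L, hp.f_unbound, hp.f_bound, hp.ec50, hp.h)
        df = pd.DataFrame({"concentration": L, "signal": clean})
        df["signal"] = clean + noise_sd * rng.standard_normal(len(df))
    elif model == "spr":
        kp = KineticParams(params["k_a"], params["k_d"], params["r_max"])
        concs = np.asarray(design.get("concentrations", [1, 5, 25, 100, 200]),
                           dtype=float)
        t_assoc = float(design.get("t_assoc", 120.0))
        t_total = float(design.get("t_total", 300.0))
        dt = float(design.get("dt", 1.0))
        t = np.arange(0.0, t_total + dt / 2, dt)
        frames = []
        for c in concs:
            clean = spr_trace(kp, c, t, t_assoc)
            noisy = clean + noise_sd * rng.standard_normal(len(t))
            frames.append(
                pd.DataFrame({"concentration": c, "time": t, "response": noisy})
            )
        df = pd.concat(frames, ignore_index=True)
        design["t_assoc"] = t_assoc
    elif model == "frap":
        fp = FrapParams(**params)
        t_max = float(design.get("t_max", 10.0))  # minutes
        dt = float(design.get("dt", 1.0 / 6.0))  # 10 s frames
        t = np.arange(0.0, t_max + dt / 2, dt)
        clean = frap_curve(t, fp.plateau, fp.k)
        df = pd.DataFrame({"time": t, "intensity": clean})
        df["intensity"] = clean + noise_sd * rng.standard_normal(len(t))
    else:
        raise ValueError(f"unknown model {model!r}")
    truth = {"model": model, "params": dict(params), "design": design,
             "noise_sd": noise_sd}
    return df, truth


# ------------------------------------------------------------------- images


def simulate_droplet_image(
    width: int,
    height: int,
    disks: list,
    background_level: float = 1000.0,
    foreground_level: float = 10000.0,
    noise_sd: float = 300.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict]:
    """16-bit grayscale image of disk-shaped droplets on a noisy background.

    ``disks`` is a list of (cx, cy, r) in pixels; a pixel belongs to a disk
    if its center lies within the radius. The truth record lists per-disk
    analytic areas pi r^2 and the exact rasterized pixel counts.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else component_rng(seed, "images")
    )
    for cx, cy, r in disks:
        if not (0 <= cx < width and 0 <= cy < height) or r <= 0:
            raise ValueError(f"disk ({cx},{cy},r={r}) out of bounds")
    img = np.full((height, width), background_level, dtype=float)
    yy, xx = np.mgrid[0:height, 0:width]
    pixel_counts = []
    for cx, cy, r in disks:
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[mask] = foreground_level
        pixel_counts.append(int(mask.sum()))
    img += noise_sd * rng.standard_normal(img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = {
        "disks": [(float(cx), float(cy), float(r)) for cx, cy, r in disks],
        "analytic_areas_px2": [float(np.pi * r * r) for _, _, r in disks],
        "rasterized_pixel_counts": pixel_counts,
        "background_level": background_level,
        "foreground_level": foreground_level,
        "noise_sd": noise_sd,
    }
    return img, truth


# ----------------------------------------------------------------- Cq tables


def simulate_cq_table(
    planted_log2fc: dict,
    ref_genes=("RPLP0", "RPS18"),
    treated_condition: str = "treated",
    control_condition: str = "control",
    bio_reps: int = 2,
    tech_reps: int = 3,
    sd: float = 0.15,
    plate_offset_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Cq table consistent with the ddCq model: one planted log2FC unit is
    one Cq cycle (treated Cq lower by log2FC).

    Reference genes must carry planted log2FC = 0. A per-(condition,
    biological replicate) plate offset is added; it cancels in dCq.
    """
    rng = seed if isinstance(seed, np.random.Generator) else component_rng(seed, "cq")
    planted = dict(planted_log2fc)
    for ref in ref_genes:
        if planted.get(ref, 0.0) != 0.0:
            raise ValueError(f"reference gene {ref!r} must have planted log2FC 0")
        planted.setdefault(ref, 0.0)
    base = {g: float(rng.uniform(18, 28)) for g in planted}
    rows = []
    for condition in (control_condition, treated_condition):
        for b in range(1, bio_reps + 1):
            plate = float(plate_offset_sd * rng.standard_normal())
            for gene, lfc in planted.items():
                mean_cq = base[gene] + plate
                if condition == treated_condition:
                    mean_cq -= lfc
                for tr in range(1, tech_reps + 1):
                    rows.append(
                        (
                            gene,
                            condition,
                            b,
                            tr,
                            mean_cq + sd * float(rng.standard_normal()),
                        )
                    )
    df = pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "cq"])
    truth = {
        "planted_log2fc": planted,
        "base_cq": base,
        "ref_genes": tuple(ref_genes),
        "sd": sd,
        "plate_offset_sd": plate_offset_sd,
    }
    return df, truth
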