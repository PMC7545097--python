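"""Synthetic-data generators mirroring each analysis stage's inputs.

Every generator is a pure function of its parameters and an integer seed
(no global random state) and returns the ground truth alongside the data,
so that pipeline recovery can be scored exactly:

* protein pairs with controlled lysine content whose digestion peptides
  occur at unique offsets (so residue mapping is unambiguous);
* cross-link identification tables with planted true links (passing
  E-values and fragment-ion runs) and decoys that each violate one
  curation rule by construction;
* one-site binding curves with multiplicative log-normal noise
  (immunoassay-like);
* microscopy fields with elliptical nuclei, Gaussian foci and a background
  gradient, for the PLA-foci and N/C-ratio pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .binding import BindingCurve, one_site
from .imaging import ImageField
from .proteinmodel import DigestSpec, Peptide, ProteinRecord, digest_in_silico
from .xlink_core import PeptideIdentification, SpectrumAnnotation

__all__ = [
    "SynthXlinkTruth",
    "SynthImageTruth",
    "synth_protein_pair",
    "plant_links",
    "synth_xlink_dataset",
    "synth_binding_curves",
    "make_pla_truth",
    "synth_pla_image",
    "synth_nc_image",
]

_RESIDUES = "ACDFGHILMNPQSTVWY"  # K, R, E added separately to control digestion


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Proteins

def synth_protein_pair(
    seed: int,
    length_a: int = 344,
    length_b: int = 308,
    n_lysines: int = 14,
    names: tuple[str, str] = ("SYNA", "SYNB"),
    domain_layout: Sequence = (),
    max_retries: int = 50,
) -> tuple[ProteinRecord, ProteinRecord]:
    """Generate a reproducible protein pair with exactly ``n_lysines`` K each.

    Default lengths mirror the C-terminally truncated constructs used for
    cross-linking (344 and 308 residues). Cleavable residues (K, R, E) are
    salted in at realistic density; the pair is regenerated until every
    trypsin/Glu-C peptide of length >= 5 (any missed-cleavage count up to
    the search maximum) occurs at a unique offset within its protein.
    """
    if min(length_a, length_b) < 50:
        raise ValueError("protein length must be >= 50")
    rng = _rng(seed)
    spec = DigestSpec()
    for _ in range(max_retries):
        prot_a = _random_protein(rng, names[0], length_a, n_lysines)
        prot_b = _random_protein(rng, names[1], length_b, n_lysines)
        if _unique_peptides(prot_a, spec) and _unique_peptides(prot_b, spec):
            if domain_layout:
                prot_a.domains = list(domain_layout)
            return prot_a, prot_b
    raise RuntimeError("could not satisfy peptide-offset uniqueness; "
                       "increase length or retries")


def _random_protein(rng, name: str, length: int, n_lysines: int) -> ProteinRecord:
    seq = rng.choice(list(_RESIDUES), size=length)
    n_re = max(2, length // 12)
    special = rng.choice(length, size=min(length, n_lysines + 2 * n_re), replace=False)
    for i, pos in enumerate(special):
        seq[pos] = "K" if i < n_lysines else ("R" if i % 2 else "E")
    return ProteinRecord(name, "".join(seq))


def _unique_peptides(protein: ProteinRecord, spec: DigestSpec) -> bool:
    for pep in digest_in_silico(protein, spec):
        if len(pep) >= 5 and protein.sequence.count(pep.sequence) != 1:
            return False
    return True


# ---------------------------------------------------------------------------
# Cross-link identifications

@dataclass
class SynthXlinkTruth:
    """Planted cross-links and rule-violating decoys for a protein pair."""

    proteins: tuple[ProteinRecord, ProteinRecord]
    true_links: list[tuple[str, int, str, int, str]]
    decoys: list[tuple[str, int, str, int, str]]
    replicate_labels: tuple[str, ...] = ("R1", "R2")
    evalue_true: tuple[float, float] = (1e-8, 1e-4)
    evalue_decoy: tuple[float, float] = (1e-3, 1.0)


def plant_links(
    proteins: tuple[ProteinRecord, ProteinRecord],
    n_true: int = 10,
    n_decoys: int = 10,
    loop_fraction: float = 0.2,
    seed: int = 0,
) -> SynthXlinkTruth:
    """Choose random lysine pairs as true links and disjoint pairs as decoys.

    True links mix inter-, intra- and loop-class sites (loop sites are two
    lysines close enough in sequence to share a peptide); decoys use
    different residue pairs so recovery can be scored exactly.
    """
    rng = _rng(seed)
    by_name = {p.name: p for p in proteins}
    pairs: list[tuple[str, int, str, int, str]] = []
    seen: set[tuple] = set()
    spec = DigestSpec()
    attempts = 0
    while len(pairs) < n_true + n_decoys and attempts < 10000:
        attempts += 1
        if rng.random() < loop_fraction:
            prot = proteins[int(rng.integers(2))]
            loops = _loop_candidates(prot, spec)
            if not loops:
                continue
            ra, rb = loops[int(rng.integers(len(loops)))]
            entry = (prot.name, ra, prot.name, rb, "loop")
        else:
            pa, pb = (proteins if rng.random() < 0.5
                      else (proteins[0], proteins[0]))
            if not pa.lysines or not pb.lysines:
                continue
            ra = int(rng.choice(pa.lysines[:-1] or pa.lysines))
            rb = int(rng.choice(pb.lysines[:-1] or pb.lysines))
            if pa.name == pb.name and ra == rb:
                continue
            cls = "inter" if pa.name != pb.name else "intra"
            a, b = sorted([(pa.name, ra), (pb.name, rb)])
            entry = (a[0], a[1], b[0], b[1], cls)
        if entry[:4] in seen:
            continue
        if _link_peptides(by_name, entry, spec) is None:
            continue
        seen.add(entry[:4])
        pairs.append(entry)
    if len(pairs) < n_true + n_decoys:
        raise RuntimeError("could not plant enough distinct links")
    return SynthXlinkTruth(proteins=proteins, true_links=pairs[:n_true],
                           decoys=pairs[n_true:])


def _loop_candidates(protein: ProteinRecord, spec: DigestSpec) -> list[tuple[int, int]]:
    out = []
    ks = protein.lysines
    for i in range(len(ks) - 1):
        if 0 < ks[i + 1] - ks[i] <= 8 and ks[i + 1] < len(protein):
            out.append((ks[i], ks[i + 1]))
    return out


def _peptide_covering(
    protein: ProteinRecord, residues: tuple[int, ...], spec: DigestSpec,
    min_len: int = 5,
) -> Peptide | None:
    """Shortest digestion peptide containing all linked residues, with the
    linked lysines treated as blocked (uncleavable) sites."""
    blocked = DigestSpec(
        enzymes=spec.enzymes, max_missed=spec.max_missed,
        gluc_cleaves_d=spec.gluc_cleaves_d, proline_block=spec.proline_block,
        blocked_sites=frozenset(residues) | spec.blocked_sites,
    )
    candidates = [
        pep for pep in digest_in_silico(protein, blocked)
        if all(pep.start <= r <= pep.end for r in residues)
        and all(r != pep.end for r in residues)  # linked K is never C-terminal
        and len(pep) >= min_len
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (len(p), p.start))


def _link_peptides(by_name, entry, spec) -> tuple[Peptide, Peptide | None] | None:
    prot_a, ra, prot_b, rb, cls = entry
    if cls == "loop":
        pep = _peptide_covering(by_name[prot_a], (ra, rb), spec)
        return None if pep is None else (pep, None)
    pa = _peptide_covering(by_name[prot_a], (ra,), spec)
    pb = _peptide_covering(by_name[prot_b], (rb,), spec)
    if pa is None or pb is None:
        return None
    return pa, pb


def _passing_ions(rng, len_a: int, len_b: int | None) -> SpectrumAnnotation:
    def run(length):
        start = int(rng.integers(1, max(2, length - 4)))
        return tuple(range(start, min(start + 4 + int(rng.integers(0, 3)), length)))

    total = 40
    assigned = int(rng.integers(24, 37))
    return SpectrumAnnotation(
        matched_y_a=run(len_a),
        matched_b_a=tuple(sorted(rng.choice(
            np.arange(1, len_a), size=min(3, len_a - 1), replace=False))),
        matched_y_b=run(len_b) if len_b else (),
        n_peaks_total=total, n_peaks_assigned=assigned,
    )


def _failing_ions(len_a: int, len_b: int | None) -> SpectrumAnnotation:
    # longest run capped at 3 in both series of both peptides
    def broken(length):
        return tuple(x for x in (1, 2, 3, 5, 6, 7) if x < length)[:4]

    return SpectrumAnnotation(
        matched_y_a=broken(len_a), matched_b_a=(),
        matched_y_b=broken(len_b) if len_b else (),
        n_peaks_total=40, n_peaks_assigned=30,
    )


def _loguniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def synth_xlink_dataset(
    truth: SynthXlinkTruth,
    digest: DigestSpec = DigestSpec(),
    seed: int = 0,
) -> list[PeptideIdentification]:
    """Emit spectrum-level identifications for planted links and decoys.

    Each true link yields 1–3 records spread over the replicate labels,
    with E-values drawn log-uniformly from the confident range and ion
    annotations satisfying every curation rule. Each decoy yields one
    record violating exactly one rule, cycling through: non-confident
    E-value, broken consecutive-ion run, and minority peak assignment.
    """
    rng = _rng(seed)
    by_name = {p.name: p for p in truth.proteins}
    records: list[PeptideIdentification] = []
    for entry in truth.true_links:
        peps = _link_peptides(by_name, entry, digest)
        if peps is None:
            raise ValueError(f"true link {entry} has no covering peptide")
        n_rec = int(rng.integers(1, 4))
        reps = list(truth.replicate_labels)
        rng.shuffle(reps)
        labels = [reps[i % len(reps)] for i in range(n_rec)]
        for rep in labels:
            records.append(_make_record(
                entry, peps, rep,
                evalue=_loguniform(rng, *truth.evalue_true),
                ions=_passing_ions(rng, len(peps[0]),
                                   len(peps[1]) if peps[1] else None),
            ))
    for i, entry in enumerate(truth.decoys):
        peps = _link_peptides(by_name, entry, digest)
        if peps is None:
            raise ValueError(f"decoy {entry} has no covering peptide")
        mode = i % 3
        len_b = len(peps[1]) if peps[1] else None
        if mode == 0:
            evalue = _loguniform(rng, *truth.evalue_decoy)
            ions = _passing_ions(rng, len(peps[0]), len_b)
        elif mode == 1:
            evalue = _loguniform(rng, *truth.evalue_true)
            ions = _failing_ions(len(peps[0]), len_b)
        else:
            evalue = _loguniform(rng, *truth.evalue_true)
            good = _passing_ions(rng, len(peps[0]), len_b)
            ions = SpectrumAnnotation(
                matched_b_a=good.matched_b_a, matched_y_a=good.matched_y_a,
                matched_b_b=good.matched_b_b, matched_y_b=good.matched_y_b,
                n_peaks_total=40, n_peaks_assigned=12,
            )
        rep = truth.replicate_labels[int(rng.integers(len(truth.replicate_labels)))]
        records.append(_make_record(entry, peps, rep, evalue=evalue, ions=ions))
    rng.shuffle(records)
    return records


def _make_record(entry, peps, replicate, evalue, ions) -> PeptideIdentification:
    prot_a, ra, prot_b, rb, cls = entry
    pep_a, pep_b = peps
    if cls == "loop":
        return PeptideIdentification(
            peptide_a=pep_a.sequence, pos_a=ra - pep_a.start + 1,
            pos_b=rb - pep_a.start + 1, peptide_b=None,
            protein_a=prot_a, protein_b=prot_a,
            residue_a=ra, residue_b=rb,
            evalue=evalue, replicate=replicate, ions=ions,
        )
    return PeptideIdentification(
        peptide_a=pep_a.sequence, pos_a=ra - pep_a.start + 1, protein_a=prot_a,
        peptide_b=pep_b.sequence, pos_b=rb - pep_b.start + 1, protein_b=prot_b,
        residue_a=ra, residue_b=rb,
        evalue=evalue, replicate=replicate, ions=ions,
    )


# ---------------------------------------------------------------------------
# Binding curves

def synth_binding_curves(
    kd: float,
    bmax: float = 1.0,
    baseline: float = 0.0,
    doses: np.ndarray | None = None,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> BindingCurve:
    """Simulate a one-site dose–response with multiplicative log-normal noise.

    The default dose series spans 0.23–500 nM (the ELISA titration range)
    in 10 log-spaced steps. ``noise_cv`` is the coefficient of variation of
    the unit-mean log-normal noise factor.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    if doses is None:
        doses = np.geomspace(0.23, 500.0, 10)
    doses = np.sort(np.asarray(doses, dtype=float))
    clean = one_site(doses, kd, bmax, baseline)
    if noise_cv == 0:
        signals = np.tile(clean, (n_replicates, 1))
    else:
        sigma = math.sqrt(math.log(1 + noise_cv**2))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma,
                                size=(n_replicates, doses.size))
        signals = clean * factors
    return BindingCurve(doses=doses, signals=signals)


# ---------------------------------------------------------------------------
# Microscopy fields

@dataclass
class SynthImageTruth:
    """Planted geometry of one synthetic field."""

    shape: tuple[int, int]
    nuclei: list[tuple[float, float, float, float]]  # (row, col, r_row, r_col)
    foci: list[tuple[int, int, bool]]  # (row, col, is_nuclear)
    amplitude: float = 80.0
    spot_sigma: float = 1.5
    noise_sd: float = 2.0
    background: tuple[float, float] = (8.0, 20.0)  # gradient endpoints
    nucleus_intensity: float = 150.0
    seed: int = 0

    @property
    def n_nuclear(self) -> int:
        return sum(1 for *_, inside in self.foci if inside)

    @property
    def n_cytoplasmic(self) -> int:
        return sum(1 for *_, inside in self.foci if not inside)


def _nucleus_mask(truth: SynthImageTruth) -> np.ndarray:
    mask = np.zeros(truth.shape, dtype=bool)
    for r, c, rr, rc in truth.nuclei:
        ridx, cidx = draw_ellipse(r, c, rr, rc, shape=truth.shape)
        mask[ridx, cidx] = True
    return mask


def make_pla_truth(
    n_nuclei: int = 3,
    n_nuclear_foci: int = 12,
    n_cyto_foci: int = 5,
    shape: tuple[int, int] = (192, 192),
    amplitude: float = 80.0,
    noise_sd: float = 2.0,
    min_separation: float = 15.0,
    seed: int = 0,
    max_retries: int = 200,
) -> SynthImageTruth:
    """Plant non-overlapping elliptical nuclei and well-separated foci.

    Nuclear foci are placed with a safety margin inside an ellipse and
    cytoplasmic foci with a margin outside every ellipse, so the planted
    inside/outside flags are unambiguous; foci keep a minimum pairwise
    separation so detections map one-to-one onto plants.
    """
    rng = _rng(seed)
    h, w = shape
    for _ in range(max_retries):
        nuclei = []
        ok = True
        for _ in range(n_nuclei):
            rr = float(rng.uniform(16, 24))
            rc = float(rng.uniform(16, 24))
            r = float(rng.uniform(rr + 6, h - rr - 6))
            c = float(rng.uniform(rc + 6, w - rc - 6))
            if any(np.hypot(r - r2, c - c2) < (max(rr, rc) + max(rr2, rc2) + 8)
                   for r2, c2, rr2, rc2 in nuclei):
                ok = False
                break
            nuclei.append((r, c, rr, rc))
        if not ok:
            continue
        truth = SynthImageTruth(shape=shape, nuclei=nuclei, foci=[],
                                amplitude=amplitude, noise_sd=noise_sd, seed=seed)
        mask = _nucleus_mask(truth)
        inner = ndi.binary_erosion(mask, iterations=4)
        outer = ~ndi.binary_dilation(mask, iterations=6)
        outer[:10, :] = outer[-10:, :] = outer[:, :10] = outer[:, -10:] = False
        foci: list[tuple[int, int, bool]] = []

        def place(region: np.ndarray, inside: bool, n: int) -> bool:
            rows, cols = np.nonzero(region)
            if rows.size == 0 and n > 0:
                return False
            tries = 0
            placed = 0
            while placed < n and tries < 2000:
                tries += 1
                k = int(rng.integers(rows.size))
                r, c = int(rows[k]), int(cols[k])
                if all(np.hypot(r - fr, c - fc) >= min_separation
                       for fr, fc, _ in foci):
                    foci.append((r, c, inside))
                    placed += 1
            return placed == n

        if place(inner, True, n_nuclear_foci) and place(outer, False, n_cyto_foci):
            truth.foci = foci
            return truth
    raise RuntimeError("could not place nuclei/foci without overlap")


def synth_pla_image(truth: SynthImageTruth) -> ImageField:
    """Render a two-channel PLA field (``dapi``, ``red``) from a truth record.

    DAPI carries the nuclei plus Gaussian noise; the red channel carries a
    left-to-right linear background gradient, one Gaussian spot per planted
    focus, and Gaussian noise. Identical truth records (same seed) render
    bitwise-identical rasters.
    """
    rng = _rng(truth.seed)
    h, w = truth.shape
    dapi = np.full(truth.shape, 10.0)
    dapi[_nucleus_mask(truth)] += truth.nucleus_intensity
    b0, b1 = truth.background
    red = np.tile(np.linspace(b0, b1, w), (h, 1))
    for r, c, _ in truth.foci:
        red = _add_spot(red, r, c, truth.amplitude, truth.spot_sigma)
    if truth.noise_sd > 0:
        dapi = dapi + rng.normal(0, truth.noise_sd, truth.shape)
        red = red + rng.normal(0, truth.noise_sd, truth.shape)
    return ImageField({"dapi": np.clip(dapi, 0, None),
                       "red": np.clip(red, 0, None)})


def _add_spot(img: np.ndarray, row: int, col: int, amplitude: float,
              sigma: float) -> np.ndarray:
    h, w = img.shape
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(0, row - half), min(h, row + half + 1)
    c0, c1 = max(0, col - half), min(w, col + half + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img = img.copy()
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((yy - row) ** 2 + (xx - col) ** 2) / (2 * sigma**2))
    return img


def synth_nc_image(
    nuclear_mean: float,
    cyto_mean: float,
    n_cells: int = 3,
    shape: tuple[int, int] = (192, 192),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageField, dict]:
    """Render a two-channel field (``dapi``, ``gfp``) with known N/C ratio.

    Each cell is a large ellipse (cytoplasm at ``cyto_mean``) containing a
    concentric nuclear ellipse (``nuclear_mean``, bright in DAPI). The truth
    dict carries the planted ratio and exact per-cell nucleus/cytoplasm
    masks for use as hand-drawn regions.
    """
    if min(nuclear_mean, cyto_mean) < 0:
        raise ValueError("compartment means must be >= 0")
    rng = _rng(seed)
    h, w = shape
    gfp = np.zeros(shape)
    dapi = np.full(shape, 5.0)
    nuc_masks: dict[int, np.ndarray] = {}
    cyto_masks: dict[int, np.ndarray] = {}
    centers: list[tuple[float, float]] = []
    cell_r = 30.0
    attempts = 0
    while len(centers) < n_cells and attempts < 2000:
        attempts += 1
        r = float(rng.uniform(cell_r + 4, h - cell_r - 4))
        c = float(rng.uniform(cell_r + 4, w - cell_r - 4))
        if any(np.hypot(r - r2, c - c2) < 2 * cell_r + 6 for r2, c2 in centers):
            continue
        centers.append((r, c))
        label = len(centers)
        cell = np.zeros(shape, dtype=bool)
        ridx, cidx = draw_ellipse(r, c, cell_r, cell_r * 0.85, shape=shape)
        cell[ridx, cidx] = True
        nucleus = np.zeros(shape, dtype=bool)
        ridx, cidx = draw_ellipse(r, c, cell_r * 0.45, cell_r * 0.4, shape=shape)
        nucleus[ridx, cidx] = True
        gfp[cell] = cyto_mean
        gfp[nucleus] = nuclear_mean
        dapi[nucleus] = 150.0
        nuc_masks[label] = nucleus
        cyto_masks[label] = cell & ~nucleus
    if len(centers) < n_cells:
        raise RuntimeError("could not place cells without overlap")
    if noise_sd > 0:
        gfp = np.clip(gfp + rng.normal(0, noise_sd, shape), 0, None)
        dapi = np.clip(dapi + rng.normal(0, noise_sd, shape), 0, None)
    truth = {
        "ratio": (nuclear_mean / cyto_mean) if cyto_mean > 0 else np.inf,
        "nuclear_mean": nuclear_mean,
        "cyto_mean": cyto_mean,
        "nucleus_masks": nuc_masks,
        "cytoplasm_masks": cyto_masks,
    }
    return ImageField({"dapi": dapi, "gfp": gfp}), truth
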