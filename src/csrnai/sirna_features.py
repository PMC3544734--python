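"""Feature extraction for 19-nt siRNA candidates.

Eight feature groups describe a candidate sequence, combined dimension 1424:

====== ===========================================================  ====
group  description                                                  dim
====== ===========================================================  ====
PSF    position-specific single-nucleotide rules (signed match)       20
SPSF   position-specific dinucleotide rules (signed match)            16
TD     nearest-neighbor duplex thermodynamics                         21
NGram  contiguous 2/3/4-mer occurrence counts                        336
NGSK   gap-weighted string-kernel 2/3/4-mer occurrences              336
PC     position one-hot composition (mono + adjacent di)             364
Image  texture/moment descriptors of the 9x9 disk encoding           132
Speech cepstral/linear-prediction descriptors of the bit signal      199
====== ===========================================================  ====

PSF/SPSF rules are learned from labeled training sequences by a two-sided
Fisher exact enrichment test per (position, pattern) pair; a rule is
*desired* when the pattern is enriched among effective siRNAs and
*undesired* when enriched among ineffective ones. All extractors are pure
functions of (sequence, configuration) and bitwise-reproducible.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.fft import dct, rfft
from scipy.stats import fisher_exact
from skimage.feature import graycomatrix
from skimage.filters import gabor

from .sequence_codec import (
    DISK_RADIUS,
    DISK_SIDE,
    digitize,
    normalize_sequence,
    to_disk_image,
)

logger = logging.getLogger("csrnai")

NUCLEOTIDES = "ACGT"
SIRNA_LENGTH = 19

GROUP_DIMS = {
    "PSF": 20,
    "SPSF": 16,
    "TD": 21,
    "NGram": 336,
    "NGSK": 336,
    "PC": 364,
    "Image": 132,
    "Speech": 199,
}
GROUP_ORDER = ("PSF", "SPSF", "TD", "NGram", "NGSK", "PC", "Image", "Speech")
COMBINED_DIM = 1424

# -- pinned extractor parameterization (chosen to realize the group sizes) --
GABOR_FREQUENCIES = (0.1, 0.2, 0.3, 0.4, 0.5)   # cycles/pixel, 5 scales
GABOR_N_ORIENTATIONS = 6                          # theta = k*pi/6
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)  # 4 unit offsets
ZERNIKE_MAX_ORDER = 7                             # 20 (n, m) magnitude pairs
FRAME_LENGTH = 16                                 # samples per analysis frame
FRAME_HOP = 10                                    # 76-sample signal -> 7 frames
N_MFCC = 13
N_MEL_FILTERS = 20
LPC_ORDER = 12
PLP_ORDER = 12
N_PLP_FILTERS = 15


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered numeric descriptors of one sequence."""

    group: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PSFRule:
    """One enrichment rule: a pattern at a 1-based position, with direction."""

    position: int
    pattern: str
    direction: str  # "desired" | "undesired"
    p_value: float

    def __post_init__(self) -> None:
        if self.direction not in ("desired", "undesired"):
            raise ValueError(f"bad direction {self.direction!r}")


# ---------------------------------------------------------------------------
# PSF / SPSF rule learning and application
# ---------------------------------------------------------------------------

def _patterns_for_mode(mode: str) -> tuple[list[str], int]:
    if mode == "single":
        return list(NUCLEOTIDES), 1
    if mode == "dinucleotide":
        return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)], 2
    raise ValueError(f"unknown mode {mode!r}")


def extract_psf_rules(positives, negatives, mode: str = "single", k: int = 20) -> list[PSFRule]:
    """Learn the k most significant (position, pattern) enrichment rules.

    For every position and every single-nucleotide (mode="single") or
    dinucleotide (mode="dinucleotide") pattern, a 2x2 presence table
    (present/absent x positive/negative) is scored by the two-sided Fisher
    exact test. The k smallest-p rules are returned, labeled *desired* when
    the pattern is relatively more frequent among positives and *undesired*
    otherwise. Ties break deterministically by (p, position, pattern).
    """
    positives = [normalize_sequence(s) for s in positives]
    negatives = [normalize_sequence(s) for s in negatives]
    if not positives or not negatives:
        raise ValueError("both sequence classes must be nonempty")
    length = len(positives[0])
    for s in itertools.chain(positives, negatives):
        if len(s) != length:
            raise ValueError("all training sequences must have equal length")

    patterns, width = _patterns_for_mode(mode)
    n_pos, n_neg = len(positives), len(negatives)
    scored: list[PSFRule] = []
    for position in range(1, length - width + 2):
        i = position - 1
        for pattern in patterns:
            a = sum(1 for s in positives if s[i : i + width] == pattern)
            c = sum(1 for s in negatives if s[i : i + width] == pattern)
            _, p = fisher_exact([[a, n_pos - a], [c, n_neg - c]], alternative="two-sided")
            direction = "desired" if a * n_neg >= c * n_pos else "undesired"
            scored.append(PSFRule(position, pattern, direction, float(p)))
    if k > len(scored):
        raise ValueError(f"k={k} exceeds the {len(scored)} testable (position, pattern) pairs")
    scored.sort(key=lambda r: (r.p_value, r.position, r.pattern))
    return scored[:k]


def apply_psf(residues: str, rules: list[PSFRule], group: str = "PSF") -> FeatureVector:
    """Evaluate signed rule-match features: +1 desired match, -1 undesired, 0 else."""
    seq = normalize_sequence(residues)
    if not rules:
        raise ValueError("empty rule set")
    values = np.zeros(len(rules))
    names = []
    for j, rule in enumerate(rules):
        i = rule.position - 1
        if i + len(rule.pattern) > len(seq):
            raise ValueError(
                f"rule position {rule.position} (+{len(rule.pattern)}) outside sequence"
            )
        names.append(f"p{rule.position}_{rule.pattern}_{rule.direction[0]}")
        if seq[i : i + len(rule.pattern)] == rule.pattern:
            values[j] = 1.0 if rule.direction == "desired" else -1.0
    return FeatureVector(group=group, names=tuple(names), values=values)


# ---------------------------------------------------------------------------
# N-gram and gap-weighted string-kernel features
# ---------------------------------------------------------------------------

def _words(order: int) -> list[str]:
    return ["".join(w) for w in itertools.product(NUCLEOTIDES, repeat=order)]


def ngram_features(residues: str, orders=(2, 3, 4)) -> FeatureVector:
    """Contiguous k-mer occurrence counts, overlaps included.

    Words are enumerated in lexicographic order (A<C<G<T) within each order;
    the dimension for orders {2,3,4} is 16+64+256 = 336.
    """
    seq = normalize_sequence(residues)
    names, values = [], []
    for order in orders:
        if len(seq) < order:
            raise ValueError(f"sequence shorter than order {order}")
        counts = dict.fromkeys(_words(order), 0)
        for i in range(len(seq) - order + 1):
            counts[seq[i : i + order]] += 1
        for w in _words(order):
            names.append(f"n{order}_{w}")
            values.append(float(counts[w]))
    return FeatureVector(group="NGram", names=tuple(names), values=np.array(values))


def ngsk_features(residues: str, orders=(2, 3, 4), decay: float = 0.5) -> FeatureVector:
    """Gap-weighted (general string kernel) k-mer occurrences.

    Every ordered, possibly non-contiguous match of a word contributes
    decay**gaps, where gaps = span - word length. decay=0 reduces exactly to
    the contiguous counts of :func:`ngram_features` (0**0 == 1).
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError("decay must lie in [0, 1]")
    seq = normalize_sequence(residues)
    names, values = [], []
    for order in orders:
        if len(seq) < order:
            raise ValueError(f"sequence shorter than order {order}")
        acc = dict.fromkeys(_words(order), 0.0)
        for combo in itertools.combinations(range(len(seq)), order):
            word = "".join(seq[i] for i in combo)
            gaps = combo[-1] - combo[0] + 1 - order
            acc[word] += decay ** gaps
        for w in _words(order):
            names.append(f"g{order}_{w}")
            values.append(acc[w])
    return FeatureVector(group="NGSK", names=tuple(names), values=np.array(values))


# ---------------------------------------------------------------------------
# Thermodynamic features (nearest-neighbor duplex model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NNTable:
    """Nearest-neighbor stacking free energies (kcal/mol) plus initiation."""

    stack_dG: dict
    initiation_dG: float

    def __post_init__(self) -> None:
        expected = {"".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)}
        missing = expected - set(self.stack_dG)
        if missing:
            raise ValueError(f"NN table missing stacks: {sorted(missing)}")
        for key, val in self.stack_dG.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite dG for stack {key}")


def load_nn_table(path=None) -> NNTable:
    """Load a nearest-neighbor table from TSV (columns: stack, dG).

    Without a path, the packaged RNA nearest-neighbor dG37 set is used.
    The row keyed ``init`` is the duplex initiation penalty.
    """
    if path is None:
        source = resources.files("csrnai").joinpath("data/nn_rna_dg37.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    stacks, init = {}, None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("stack"):
            continue
        key, val = line.split("\t")
        if key == "init":
            init = float(val)
        else:
            stacks[normalize_sequence(key)] = float(val)
    if init is None:
        raise ValueError("NN table has no 'init' row")
    return NNTable(stack_dG=stacks, initiation_dG=init)


def thermo_features(residues: str, nn: NNTable) -> FeatureVector:
    """Nearest-neighbor duplex free-energy profile of a 19-mer (21 values).

    The 18 positional stack dGs, the whole-duplex dG (stack sum plus
    initiation), and the mean dG of the two stacks at each duplex end (the
    5' terminus, stacks 1-2, and the 3' terminus, stacks 17-18). Low 5'-end
    stability of the guide strand is the classic thermodynamic-asymmetry
    signal of effective siRNAs.
    """
    seq = normalize_sequence(residues)
    if len(seq) != SIRNA_LENGTH:
        raise ValueError(f"thermodynamic features are defined for 19-mers, got {len(seq)}")
    stacks = np.array(
        [nn.stack_dG[seq[i : i + 2]] for i in range(SIRNA_LENGTH - 1)]
    )
    total = stacks.sum() + nn.initiation_dG
    five_prime = stacks[:2].mean()
    three_prime = stacks[-2:].mean()
    names = tuple(f"stack_{i + 1}" for i in range(SIRNA_LENGTH - 1)) + (
        "duplex_dG",
        "end5_dG",
        "end3_dG",
    )
    values = np.concatenate([stacks, [total, five_prime, three_prime]])
    return FeatureVector(group="TD", names=names, values=values)


# ---------------------------------------------------------------------------
# Position-composition features
# ---------------------------------------------------------------------------

def pc_features(residues: str) -> FeatureVector:
    """One-hot position composition: 19x4 mono plus 18x16 adjacent di (364)."""
    seq = normalize_sequence(residues)
    if len(seq) != SIRNA_LENGTH:
        raise ValueError(f"PC features are defined for 19-mers, got {len(seq)}")
    names, values = [], []
    for pos in range(SIRNA_LENGTH):
        for nt in NUCLEOTIDES:
            names.append(f"pos{pos + 1}_{nt}")
            values.append(1.0 if seq[pos] == nt else 0.0)
    dinucs = _words(2)
    for pos in range(SIRNA_LENGTH - 1):
        for dn in dinucs:
            names.append(f"pair{pos + 1}_{dn}")
            values.append(1.0 if seq[pos : pos + 2] == dn else 0.0)
    return FeatureVector(group="PC", names=tuple(names), values=np.array(values))


# ---------------------------------------------------------------------------
# Image features on the disk encoding (60 + 52 + 20 = 132)
# ---------------------------------------------------------------------------

def _haralick_13(pmat: np.ndarray) -> np.ndarray:
    """The 13 classic co-occurrence texture statistics of one normalized GLCM.

    Degenerate distributions (constant images) yield finite values: entropies
    use 0*log(0)=0 and the correlation statistics fall back to 0 when a
    marginal is deterministic.
    """
    p = pmat / pmat.sum() if pmat.sum() > 0 else pmat
    levels = p.shape[0]
    i_idx, j_idx = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (np.arange(levels) * px).sum()
    mu_y = (np.arange(levels) * py).sum()
    var_x = ((np.arange(levels) - mu_x) ** 2 * px).sum()
    var_y = ((np.arange(levels) - mu_y) ** 2 * py).sum()

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    # p_{x+y}(k), k = 0..2(levels-1); p_{x-y}(k), k = 0..levels-1
    p_sum = np.zeros(2 * levels - 1)
    np.add.at(p_sum, (i_idx + j_idx).ravel(), p.ravel())
    p_diff = np.zeros(levels)
    np.add.at(p_diff, np.abs(i_idx - j_idx).ravel(), p.ravel())

    asm = float((p ** 2).sum())
    contrast = float((((i_idx - j_idx) ** 2) * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(
            ((i_idx - mu_x) * (j_idx - mu_y) * p).sum() / math.sqrt(var_x * var_y)
        )
    else:
        correlation = 0.0
    sum_of_squares = float(var_x)
    idm = float((p / (1.0 + (i_idx - j_idx) ** 2)).sum())
    k_sum = np.arange(2 * levels - 1)
    sum_average = float((k_sum * p_sum).sum())
    sum_entropy = _ent(p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    entropy = _ent(p.ravel())
    k_diff = np.arange(levels)
    diff_average = float((k_diff * p_diff).sum())
    diff_variance = float(((k_diff - diff_average) ** 2 * p_diff).sum())
    diff_entropy = _ent(p_diff)
    hxy = entropy
    hx, hy = _ent(px), _ent(py)
    outer = np.outer(px, py)
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    mask2 = outer > 0
    hxy2 = float(-(outer[mask2] * np.log2(outer[mask2])).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    return np.array(
        [
            asm, contrast, correlation, sum_of_squares, idm, sum_average,
            sum_variance, sum_entropy, entropy, diff_variance, diff_entropy,
            imc1, imc2,
        ]
    )


_HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_avg",
    "sum_var", "sum_ent", "entropy", "diff_var", "diff_ent", "imc1", "imc2",
)


def _zernike_indices() -> list[tuple[int, int]]:
    return [
        (n, m)
        for n in range(ZERNIKE_MAX_ORDER + 1)
        for m in range(n % 2, n + 1, 2)
    ]


def _zernike_magnitudes(image: np.ndarray) -> np.ndarray:
    """Zernike moment magnitudes |A_nm| through order 7 on the inscribed disk."""
    c0 = DISK_SIDE // 2
    rows, cols = np.meshgrid(np.arange(DISK_SIDE), np.arange(DISK_SIDE), indexing="ij")
    dx = cols - c0
    dy = c0 - rows
    rho = np.sqrt(dx ** 2 + dy ** 2) / DISK_RADIUS
    theta = np.arctan2(dy, dx)
    inside = rho <= 1.0
    f = image[inside].astype(float)
    rho_in = rho[inside]
    theta_in = theta[inside]
    out = []
    for n, m in _zernike_indices():
        radial = np.zeros_like(rho_in)
        for s in range((n - m) // 2 + 1):
            coef = (
                (-1) ** s
                * math.factorial(n - s)
                / (
                    math.factorial(s)
                    * math.factorial((n + m) // 2 - s)
                    * math.factorial((n - m) // 2 - s)
                )
            )
            radial += coef * rho_in ** (n - 2 * s)
        vnm = radial * np.exp(-1j * m * theta_in)
        a = (n + 1) / math.pi * (f * vnm).sum()
        out.append(abs(a))
    return np.array(out)


def image_features(residues: str) -> FeatureVector:
    """Texture and moment descriptors of the disk-encoded sequence (132).

    Oriented band-pass (Gabor) responses at 5 spatial frequencies x 6
    orientations, summarized by mean and standard deviation of the response
    magnitude (60); the 13 co-occurrence texture statistics at the 4 unit
    pixel offsets (52); Zernike moment magnitudes through order 7 (20).
    """
    disk = to_disk_image(residues)
    img = disk.pixels.astype(float)
    names, values = [], []
    for fi, freq in enumerate(GABOR_FREQUENCIES):
        for oi in range(GABOR_N_ORIENTATIONS):
            theta = oi * math.pi / GABOR_N_ORIENTATIONS
            real, imag = gabor(img, frequency=freq, theta=theta)
            mag = np.hypot(real, imag)
            names += [f"gabor_f{fi}_o{oi}_mean", f"gabor_f{fi}_o{oi}_std"]
            values += [float(mag.mean()), float(mag.std())]
    glcm = graycomatrix(
        disk.pixels.astype(np.uint8),
        distances=[1],
        angles=list(GLCM_ANGLES),
        levels=2,
        symmetric=True,
        normed=False,
    )
    for ai in range(len(GLCM_ANGLES)):
        stats = _haralick_13(glcm[:, :, 0, ai].astype(float))
        for name, val in zip(_HARALICK_NAMES, stats):
            names.append(f"glcm_a{ai}_{name}")
            values.append(float(val))
    for (n, m), val in zip(_zernike_indices(), _zernike_magnitudes(img)):
        names.append(f"zernike_{n}_{m}")
        values.append(float(val))
    vec = np.array(values)
    assert np.all(np.isfinite(vec))
    return FeatureVector(group="Image", names=tuple(names), values=vec)


# ---------------------------------------------------------------------------
# Speech features on the digital signal (91 + 84 + 24 = 199)
# ---------------------------------------------------------------------------

def _frames(signal: np.ndarray) -> np.ndarray:
    n = 1 + (len(signal) - FRAME_LENGTH) // FRAME_HOP
    return np.stack(
        [signal[i * FRAME_HOP : i * FRAME_HOP + FRAME_LENGTH] for i in range(n)]
    )


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _triangular_bank(n_filters: int, n_bins: int, nyquist: float, warp, unwarp) -> np.ndarray:
    """Triangular filter bank with centers equally spaced on the warped axis."""
    edges = unwarp(np.linspace(warp(0.0), warp(nyquist), n_filters + 2))
    freqs = np.linspace(0.0, nyquist, n_bins)
    bank = np.zeros((n_filters, n_bins))
    for k in range(n_filters):
        lo, ctr, hi = edges[k], edges[k + 1], edges[k + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        bank[k] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion; returns the `order` prediction coefficients.

    Convention: x[t] ~ sum_k a[k] * x[t-k]. A (near-)degenerate
    autocorrelation truncates the recursion and pads with zeros.
    """
    a = np.zeros(order)
    if r[0] <= 1e-12:
        return a
    err = r[0]
    for i in range(order):
        acc = r[i + 1] - np.dot(a[:i], r[i:0:-1])
        if err <= 1e-12:
            break
        k = acc / err
        a_new = a.copy()
        a_new[i] = k
        a_new[:i] = a[:i] - k * a[i - 1 :: -1][:i]
        a = a_new
        err *= 1.0 - k * k
    return a


def _lpc(frame: np.ndarray, order: int) -> np.ndarray:
    frame = frame - frame.mean()
    n = len(frame)
    r = np.array([np.dot(frame[: n - k], frame[k:]) for k in range(order + 1)])
    if r[0] <= 1e-12:
        logger.debug("all-zero frame: linear-prediction coefficients fall back to 0")
        return np.zeros(order)
    return _levinson(r, order)


def _lpc_to_cepstrum(a: np.ndarray, n_ceps: int) -> np.ndarray:
    """Cepstral coefficients of the all-pole model via the standard recursion."""
    c = np.zeros(n_ceps)
    for n in range(1, n_ceps + 1):
        acc = a[n - 1] if n <= len(a) else 0.0
        for k in range(1, n):
            if n - k <= len(a):
                acc += (k / n) * c[k - 1] * a[n - k - 1]
        c[n - 1] = acc
    return c


def _mfcc_frame(frame: np.ndarray) -> np.ndarray:
    windowed = frame * np.hamming(len(frame))
    power = np.abs(rfft(windowed)) ** 2
    bank = _triangular_bank(N_MEL_FILTERS, len(power), 0.5, _hz_to_mel, _mel_to_hz)
    energies = np.log(np.maximum(bank @ power, 1e-12))
    ceps = dct(energies, type=2, norm="ortho")
    return ceps[1 : N_MFCC + 1]  # c0 (log-energy proxy) excluded


def _bark(f):
    f = np.asarray(f, dtype=float)
    return 6.0 * np.arcsinh(f / 0.1)  # nominal band: Nyquist 0.5 -> ~13 Bark


def _bark_inv(b):
    return 0.1 * np.sinh(np.asarray(b, dtype=float) / 6.0)


def _plp_cepstra(signal: np.ndarray) -> np.ndarray:
    """Perceptual linear-prediction cepstra (order 12) of a whole signal.

    Critical-band (Bark-warped) triangular integration of the power spectrum,
    equal-loudness weighting, cube-root intensity-loudness compression, then
    an all-pole fit to the compressed spectrum and conversion to cepstra.
    """
    x = signal.astype(float) - signal.mean()
    power = np.abs(rfft(x * np.hamming(len(x)))) ** 2
    n_bins = len(power)
    bank = _triangular_bank(N_PLP_FILTERS, n_bins, 0.5, _bark, _bark_inv)
    freqs = np.linspace(0.0, 0.5, n_bins)
    centers = bank.argmax(axis=1)
    fc = freqs[centers]
    # equal-loudness curve (simplified Makhoul/Hermansky form on the nominal band)
    eql = ((fc ** 2 + 0.01) / (fc ** 2 + 0.1)) * fc ** 2 / (fc ** 2 + 1e-4 + 1e-12)
    eql = np.maximum(eql, 1e-6)
    band = np.maximum(bank @ power, 1e-12) * eql
    compressed = band ** (1.0 / 3.0)
    # symmetric spectrum -> autocorrelation via inverse DFT
    spec = np.concatenate([compressed, compressed[-2:0:-1]])
    r = np.fft.ifft(spec).real[: PLP_ORDER + 1]
    a = _levinson(r, PLP_ORDER)
    return _lpc_to_cepstrum(a, PLP_ORDER)


def speech_features(residues: str) -> FeatureVector:
    """Cepstral and linear-prediction descriptors of the bit signal (199).

    The 76-sample digital signal is framed (length 16, hop 10 -> 7 frames).
    Per frame: 13 mel-cepstral coefficients (91) and 12 linear-prediction
    coefficients (84). On the whole signal: 12 perceptual linear-prediction
    cepstra plus their first differences between the two signal halves (24).
    """
    seq = normalize_sequence(residues)
    if len(seq) != SIRNA_LENGTH:
        raise ValueError(f"speech features are defined for 19-mers, got {len(seq)}")
    signal = digitize(seq).astype(float)
    frames = _frames(signal)
    names, values = [], []
    for t, frame in enumerate(frames):
        for i, c in enumerate(_mfcc_frame(frame)):
            names.append(f"mfcc_t{t}_c{i + 1}")
            values.append(float(c))
    for t, frame in enumerate(frames):
        for i, a in enumerate(_lpc(frame, LPC_ORDER)):
            names.append(f"lpc_t{t}_a{i + 1}")
            values.append(float(a))
    whole = _plp_cepstra(signal)
    half = len(signal) // 2
    delta = _plp_cepstra(signal[half:]) - _plp_cepstra(signal[:half])
    for i, c in enumerate(whole):
        names.append(f"plp_c{i + 1}")
        values.append(float(c))
    for i, d in enumerate(delta):
        names.append(f"plp_d{i + 1}")
        values.append(float(d))
    vec = np.array(values)
    assert np.all(np.isfinite(vec))
    return FeatureVector(group="Speech", names=tuple(names), values=vec)


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------

def combine_features(
    residues: str,
    psf_rules: list[PSFRule],
    spsf_rules: list[PSFRule],
    nn: NNTable | None = None,
    ngsk_decay: float = 0.5,
) -> FeatureVector:
    """Concatenate all eight groups in the fixed order; dimension 1424."""
    if len(psf_rules) != GROUP_DIMS["PSF"]:
        raise ValueError(f"expected {GROUP_DIMS['PSF']} PSF rules, got {len(psf_rules)}")
    if len(spsf_rules) != GROUP_DIMS["SPSF"]:
        raise ValueError(f"expected {GROUP_DIMS['SPSF']} SPSF rules, got {len(spsf_rules)}")
    nn = nn or load_nn_table()
    parts = {
        "PSF": apply_psf(residues, psf_rules, group="PSF"),
        "SPSF": apply_psf(residues, spsf_rules, group="SPSF"),
        "TD": thermo_features(residues, nn),
        "NGram": ngram_features(residues),
        "NGSK": ngsk_features(residues, decay=ngsk_decay),
        "PC": pc_features(residues),
        "Image": image_features(residues),
        "Speech": speech_features(residues),
    }
    names, values = [], []
    for group in GROUP_ORDER:
        fv = parts[group]
        if len(fv) != GROUP_DIMS[group]:
            raise ValueError(
                f"group {group} produced {len(fv)} features, expected {GROUP_DIMS[group]}"
            )
        names += [f"{group}_{n}" for n in fv.names]
        values.append(fv.values)
    combined = FeatureVector(
        group="Combined", names=tuple(names), values=np.concatenate(values)
    )
    assert len(combined) == COMBINED_DIM
    return combined


def feature_matrix(sequences, psf_rules, spsf_rules, nn=None, ngsk_decay=0.5):
    """Stack combined feature vectors for many sequences into (X, names)."""
    rows, names = [], None
    for seq in sequences:
        fv = combine_features(seq, psf_rules, spsf_rules, nn=nn, ngsk_decay=ngsk_decay)
        names = fv.names
        rows.append(fv.values)
    return np.array(rows), names
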