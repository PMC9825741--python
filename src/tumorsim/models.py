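"""Reference-model containers and their on-disk bundle format.

Three models summarize a sequencing platform as observed in control samples:

* :class:`ReadDepthModel` -- per-captured-position fragment-start weights
  (the sampling distribution for fragment placement) plus insert-size
  statistics for paired-end data;
* :class:`QualityModel` -- per-read-cycle empirical Phred-quality
  distributions;
* :class:`PositionErrorModel` -- sparse per-genomic-position systematic
  error rates with the profile of alternate bases observed there.

The bundle format is a single zip archive holding a JSON header (format
version, builder parameters, target checksum) plus ``.npy`` arrays, so a
round trip reproduces every field bit-exactly.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from tumorsim.errors import ModelError
from tumorsim.regions import TargetRegions

BUNDLE_FORMAT_VERSION = "tumorsim-models-1"

#: Phred quality values representable in a QualityModel histogram.
MAX_PHRED = 93
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ReadDepthModel:
    """Fragment-start weights over captured positions plus insert statistics.

    ``weights[i][j]`` is the (unnormalized, non-negative) number of observed
    fragment leftmost starts at offset ``j`` of target region ``i``.
    ``normalization`` is the total weight; dividing by it yields the
    fragment-start probability distribution.
    """

    targets: TargetRegions
    weights: list[np.ndarray]
    normalization: float = field(init=False)
    insert_mean: float = 0.0
    insert_sd: float = 0.0
    paired: bool = True
    read_length_observed: int = 0
    n_source_samples: int = 1

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.targets):
            raise ModelError("one weight array per target region required")
        for w, (chrom, s, e) in zip(self.weights, self.targets):
            if len(w) != e - s:
                raise ModelError(f"weight array length mismatch for {chrom}:{s}-{e}")
            if np.any(w < 0):
                raise ModelError("negative fragment-start weight")
        self.normalization = float(sum(w.sum() for w in self.weights))
        if self.insert_sd < 0:
            raise ModelError("insert_sd must be >= 0")

    def probabilities(self) -> np.ndarray:
        """Flattened fragment-start probabilities over all captured positions."""
        if self.normalization <= 0:
            raise ModelError("empty RDM: no fragment starts on target")
        flat = np.concatenate([np.asarray(w, dtype=float) for w in self.weights])
        return flat / self.normalization


@dataclass
class QualityModel:
    """Per-read-cycle empirical distribution of Phred base qualities.

    ``cycle_hist`` has shape (max_read_length, MAX_PHRED + 1); each row with
    at least one observation sums to 1.
    """

    cycle_hist: np.ndarray

    def __post_init__(self) -> None:
        self.cycle_hist = np.asarray(self.cycle_hist, dtype=float)
        if self.cycle_hist.ndim != 2 or self.cycle_hist.shape[1] != MAX_PHRED + 1:
            raise ModelError(f"cycle_hist must be (cycles, {MAX_PHRED + 1})")
        if np.any(self.cycle_hist < 0):
            raise ModelError("negative probability in quality histogram")
        sums = self.cycle_hist.sum(axis=1)
        bad = ~((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0))
        if np.any(bad):
            raise ModelError("per-cycle quality histograms must sum to 1 (or be empty)")

    @property
    def max_read_length(self) -> int:
        return self.cycle_hist.shape[0]

    def cdf(self) -> np.ndarray:
        """Per-cycle cumulative distributions, for vectorized sampling."""
        return np.cumsum(self.cycle_hist, axis=1)


@dataclass
class PositionErrorModel:
    """Sparse map of systematic-error positions.

    ``sites[(chrom, pos)] = (error_rate, {base: prob, ...})`` where ``pos``
    is 0-based and the alt-base profile covers the non-reference bases
    observed at the site.
    """

    sites: dict[tuple[str, int], tuple[float, dict[str, float]]]
    hq_base_quality_min: int = 20
    hq_mapping_quality_min: int = 20
    min_depth: int = 50

    def __post_init__(self) -> None:
        for (chrom, pos), (rate, profile) in self.sites.items():
            if not (0.0 < rate <= 1.0):
                raise ModelError(f"error rate out of (0,1] at {chrom}:{pos}")
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ModelError(f"alt-base profile does not sum to 1 at {chrom}:{pos}")
            if any(p < 0 for p in profile.values()):
                raise ModelError(f"negative alt-base probability at {chrom}:{pos}")

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.sites


def targets_checksum(targets: TargetRegions) -> str:
    text = "\n".join(f"{c}\t{s}\t{e}" for c, s, e in targets)
    return hashlib.sha256(text.encode()).hexdigest()


def _put_array(zf: zipfile.ZipFile, name: str, arr: np.ndarray) -> None:
    buf = io.BytesIO()
    np.save(buf, arr, allow_pickle=False)
    zf.writestr(name, buf.getvalue())


def _get_array(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    with zf.open(name) as fh:
        return np.load(io.BytesIO(fh.read()), allow_pickle=False)


def save_models(
    rdm: ReadDepthModel,
    qm: QualityModel,
    pbe: PositionErrorModel,
    path: str,
    builder_params: dict | None = None,
) -> None:
    """Serialize the three models into a single bundle archive."""
    header = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "builder_params": builder_params or {},
        "targets": [[c, s, e] for c, s, e in rdm.targets],
        "targets_sha256": targets_checksum(rdm.targets),
        "rdm": {
            "insert_mean": rdm.insert_mean,
            "insert_sd": rdm.insert_sd,
            "paired": rdm.paired,
            "read_length_observed": rdm.read_length_observed,
            "n_source_samples": rdm.n_source_samples,
        },
        "pbe": {
            "hq_base_quality_min": pbe.hq_base_quality_min,
            "hq_mapping_quality_min": pbe.hq_mapping_quality_min,
            "min_depth": pbe.min_depth,
            "chroms": [chrom for (chrom, _), _ in sorted(pbe.sites.items())],
        },
    }
    site_items = sorted(pbe.sites.items())
    positions = np.array([pos for (_, pos), _ in site_items], dtype=np.int64)
    rates = np.array([rate for _, (rate, _) in site_items], dtype=float)
    profiles = np.zeros((len(site_items), 4), dtype=float)
    for i, (_, (_, profile)) in enumerate(site_items):
        for base, p in profile.items():
            profiles[i, BASE_INDEX[base]] = p
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for i, w in enumerate(rdm.weights):
            _put_array(zf, f"rdm/weights_{i}.npy", np.asarray(w, dtype=float))
        _put_array(zf, "qm/cycle_hist.npy", qm.cycle_hist)
        _put_array(zf, "pbe/positions.npy", positions)
        _put_array(zf, "pbe/rates.npy", rates)
        _put_array(zf, "pbe/profiles.npy", profiles)


def load_models(path: str) -> tuple[ReadDepthModel, QualityModel, PositionErrorModel]:
    """Load a model bundle written by :func:`save_models`."""
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, OSError) as exc:
        raise ModelError(f"corrupt or unreadable model bundle {path!r}: {exc}") from exc
    with zf:
        try:
            header = json.loads(zf.read("header.json"))
        except (KeyError, json.JSONDecodeError) as exc:
            raise ModelError(f"corrupt model bundle {path!r}: bad header") from exc
        version = header.get("format_version")
        if version != BUNDLE_FORMAT_VERSION:
            raise ModelError(
                f"unsupported model-bundle version {version!r} "
                f"(this build reads {BUNDLE_FORMAT_VERSION!r})"
            )
        targets = TargetRegions(tuple((c, s, e) for c, s, e in header["targets"]))
        try:
            weights = [
                _get_array(zf, f"rdm/weights_{i}.npy") for i in range(len(targets))
            ]
            cycle_hist = _get_array(zf, "qm/cycle_hist.npy")
            positions = _get_array(zf, "pbe/positions.npy")
            rates = _get_array(zf, "pbe/rates.npy")
            profiles = _get_array(zf, "pbe/profiles.npy")
        except (KeyError, ValueError, OSError) as exc:
            raise ModelError(f"corrupt model bundle {path!r}: {exc}") from exc
    meta = header["rdm"]
    rdm = ReadDepthModel(
        targets=targets,
        weights=weights,
        insert_mean=meta["insert_mean"],
        insert_sd=meta["insert_sd"],
        paired=meta["paired"],
        read_length_observed=meta["read_length_observed"],
        n_source_samples=meta["n_source_samples"],
    )
    qm = QualityModel(cycle_hist=cycle_hist)
    pbe_meta = header["pbe"]
    sites: dict[tuple[str, int], tuple[float, dict[str, float]]] = {}
    for chrom, pos, rate, prof in zip(
        pbe_meta["chroms"], positions, rates, profiles
    ):
        profile = {BASES[i]: float(p) for i, p in enumerate(prof) if p > 0}
        sites[(chrom, int(pos))] = (float(rate), profile)
    pbe = PositionErrorModel(
        sites=sites,
        hq_base_quality_min=pbe_meta["hq_base_quality_min"],
        hq_mapping_quality_min=pbe_meta["hq_mapping_quality_min"],
        min_depth=pbe_meta["min_depth"],
    )
    return rdm, qm, pbe
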