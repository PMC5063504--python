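"""Stable on-disk formats for spectra, titrations, distributions and results.

Spectra are CSV (``wavelength_nm,intensity``), one file per scan, with a
sidecar JSON manifest carrying the metadata (excitation wavelength,
condition, construct, ground truth when simulated).  Titration series are
TSV ``ion,pX,replicate,response``; sedimentation distributions TSV
``s,frequency``; fit and end-point summaries JSON.  Floats are serialized
with full round-trip precision.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import TitrationSeries
from .simulate import EndpointDataset
from .spectra import DirectExcitationProfile, ReferenceSpectra, Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_titration_tsv",
    "read_titration_tsv",
    "write_auc_tsv",
    "read_auc_tsv",
    "write_endpoint_dataset",
    "read_endpoint_dataset",
    "write_json",
]

MIN_POINTS = 50  # unmixing over the scan window needs a real spectrum, not a stub


class SpectrumParseError(ValueError):
    pass


def write_spectrum_csv(
    spectrum: Spectrum, path: str | Path, manifest: bool = True
) -> Path:
    """Write one scan as CSV plus a sidecar ``<stem>.json`` manifest."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "intensity"])
        for w, i in zip(spectrum.wavelength_nm, spectrum.intensity):
            writer.writerow([repr(float(w)), repr(float(i))])
    if manifest:
        meta = {
            "excitation_nm": spectrum.excitation_nm,
            "condition": spectrum.condition,
            "construct_id": spectrum.construct_id,
            "ground_truth": spectrum.ground_truth,
        }
        write_json(meta, path.with_suffix(".json"))
    return path


def read_spectrum_csv(path: str | Path, manifest_path: str | Path | None = None) -> Spectrum:
    """Read a scan CSV; metadata comes from the sidecar manifest if present.

    Parse errors (missing columns, non-numeric or NaN rows, unsorted grid,
    too few points) are reported with the offending line number.
    """
    path = Path(path)
    wl, inten = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["wavelength_nm", "intensity"]:
            raise SpectrumParseError(
                f"{path}: line 1: expected header 'wavelength_nm,intensity', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise SpectrumParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                w, i = float(row[0]), float(row[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value ({row[0]!r}, {row[1]!r})"
                ) from exc
            if math.isnan(w) or math.isnan(i) or math.isinf(w) or math.isinf(i):
                raise SpectrumParseError(f"{path}: line {lineno}: non-finite value")
            if wl and w <= wl[-1]:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: wavelength {w} not strictly increasing"
                )
            wl.append(w)
            inten.append(i)
    if len(wl) < MIN_POINTS:
        raise SpectrumParseError(
            f"{path}: insufficient points ({len(wl)} < {MIN_POINTS}) for unmixing"
        )

    meta: dict = {}
    mpath = Path(manifest_path) if manifest_path else path.with_suffix(".json")
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    return Spectrum(
        wavelength_nm=np.array(wl),
        intensity=np.array(inten),
        excitation_nm=float(meta.get("excitation_nm", float("nan"))),
        condition=meta.get("condition", ""),
        construct_id=meta.get("construct_id", ""),
        ground_truth=meta.get("ground_truth"),
    )


def write_titration_tsv(series: TitrationSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "ion": series.ion,
            "pX": series.pX,
            "replicate": series.replicate,
            "response": series.response,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_titration_tsv(
    path: str | Path, response_kind: str = "fret_ratio", construct_id: str = ""
) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t")
    required = {"ion", "pX", "replicate", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    ions = df["ion"].unique()
    if len(ions) != 1:
        raise ValueError(f"{path}: expected a single ion, found {list(ions)}")
    return TitrationSeries(
        ion=str(ions[0]),
        pX=df["pX"].to_numpy(float),
        response=df["response"].to_numpy(float),
        replicate=df["replicate"].to_numpy(),
        response_kind=response_kind,
        construct_id=construct_id,
    )


def write_auc_tsv(s: np.ndarray, frequency: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"s": s, "frequency": frequency}).to_csv(path, sep="\t", index=False)
    return path


def read_auc_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    missing = {"s", "frequency"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df["s"].to_numpy(float), df["frequency"].to_numpy(float)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path


# -------------------------------------------------------- end-point datasets
def _scan_name(prefix: str, label: str, ex: float) -> str:
    safe = label.replace("/", "_").replace(" ", "_")
    return f"{prefix}__{safe}__{ex:g}nm.csv"


def write_endpoint_dataset(dataset: EndpointDataset, outdir: str | Path) -> Path:
    """Write an end-point dataset as a directory of scan CSVs + manifest.

    The reference spectra are written alongside (``donor_ref.csv``,
    ``acceptor_ref.csv``) so the directory is self-contained for analysis.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = dataset.references
    for name, shape in (("donor_ref", refs.donor_emission), ("acceptor_ref", refs.acceptor_emission)):
        write_spectrum_csv(
            Spectrum(refs.wavelength_nm, shape, excitation_nm=0.0, condition="reference"),
            outdir / f"{name}.csv",
            manifest=False,
        )

    files: dict = {"scans": {}, "sample_direct": {}, "controls": {}}
    for label, by_ex in dataset.scans.items():
        files["scans"][label] = {}
        for ex, spec in by_ex.items():
            fname = _scan_name("scan", label, ex)
            write_spectrum_csv(spec, outdir / fname)
            files["scans"][label][repr(float(ex))] = fname
    for label, spec in dataset.sample_direct_scans.items():
        fname = _scan_name("direct", label, spec.excitation_nm)
        write_spectrum_csv(spec, outdir / fname)
        files["sample_direct"][label] = fname
    for ex, spec in dataset.control_scans.items():
        fname = _scan_name("control", "acc_only", ex)
        write_spectrum_csv(spec, outdir / fname)
        files["controls"][repr(float(ex))] = fname

    manifest = {
        "construct_id": dataset.construct.construct_id,
        "active_sites": sorted(dataset.construct.active_sites),
        "protocol": dataset.protocol,
        "condition_order": list(dataset.condition_order),
        "true_fr": dataset.true_fr,
        "true_delta_fr": dataset.true_delta_fr,
        "direct_profile": {
            "peak_nm": refs.direct_profile.peak_nm,
            "log_width": refs.direct_profile.log_width,
            "domain_nm": list(refs.direct_profile.domain_nm),
        },
        "donor_peak_nm": refs.donor_peak_nm,
        "acceptor_peak_nm": refs.acceptor_peak_nm,
        "files": files,
    }
    write_json(manifest, outdir / "manifest.json")
    return outdir


def read_endpoint_dataset(indir: str | Path) -> EndpointDataset:
    """Read back a dataset directory written by :func:`write_endpoint_dataset`."""
    from .decomposition import ConstructDesign  # local import to avoid cycles

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    donor = read_spectrum_csv(indir / "donor_ref.csv")
    acceptor = read_spectrum_csv(indir / "acceptor_ref.csv")
    dp = manifest["direct_profile"]
    refs = ReferenceSpectra(
        wavelength_nm=donor.wavelength_nm,
        donor_emission=donor.intensity,
        acceptor_emission=acceptor.intensity,
        direct_profile=DirectExcitationProfile(
            peak_nm=dp["peak_nm"], log_width=dp["log_width"], domain_nm=tuple(dp["domain_nm"])
        ),
        donor_peak_nm=manifest["donor_peak_nm"],
        acceptor_peak_nm=manifest["acceptor_peak_nm"],
    )
    files = manifest["files"]
    scans = {
        label: {float(ex): read_spectrum_csv(indir / fname) for ex, fname in by_ex.items()}
        for label, by_ex in files["scans"].items()
    }
    sample_direct = {
        label: read_spectrum_csv(indir / fname)
        for label, fname in files["sample_direct"].items()
    }
    controls = {
        float(ex): read_spectrum_csv(indir / fname)
        for ex, fname in files["controls"].items()
    }
    return EndpointDataset(
        construct=ConstructDesign(
            manifest["construct_id"], frozenset(manifest["active_sites"])
        ),
        protocol=manifest["protocol"],
        condition_order=tuple(manifest["condition_order"]),
        scans=scans,
        sample_direct_scans=sample_direct,
        control_scans=controls,
        references=refs,
        true_fr=manifest["true_fr"],
        true_delta_fr=manifest["true_delta_fr"],
    )
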