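"""Reading and writing pipeline artifacts.

The portable interchange formats are plain text: one TSV peak list per
sample (``m/z``, ``intensity`` columns, with sample id/role/batch carried in
``#key=value`` header lines), a manifest TSV mapping sample id → file →
role, TSV clinical tables, lipid libraries and feature matrices, and a JSON
run manifest. mzML reading is supported behind the same contract (scans are
merged, since direct infusion has no retention-time dimension).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import FeatureMatrix, LipidTarget, Role, Spectrum

__all__ = [
    "write_peaklist",
    "read_peaklist",
    "write_spectra",
    "read_peaklists",
    "read_mzml",
    "write_library",
    "read_library",
    "write_clinical",
    "read_clinical",
    "write_matrix",
    "read_matrix",
    "write_json",
]


def write_peaklist(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#sample_id={spectrum.sample_id}\n")
        fh.write(f"#role={spectrum.role.value}\n")
        fh.write(f"#batch={spectrum.batch}\n")
        fh.write("mz\tintensity\n")
        for mz, inten in spectrum.peaks:
            fh.write(f"{mz:.17g}\t{inten:.17g}\n")
    return path


def read_peaklist(path: str | Path) -> Spectrum:
    path = Path(path)
    meta = {"sample_id": path.stem, "role": "sample", "batch": "b1"}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("mz"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            rows.append((float(parts[0]), float(parts[1])))
    try:
        role = Role(meta["role"])
    except ValueError as exc:
        raise ValueError(f"{path}: unknown role {meta['role']!r}") from exc
    arr = np.array(rows, dtype=float).reshape(-1, 2)
    if arr.shape[0] > 1:
        diffs = np.diff(arr[:, 0])
        if np.any(diffs <= 0):
            bad = int(np.flatnonzero(diffs <= 0)[0]) + 2
            raise ValueError(f"{path}: m/z not strictly increasing at data row {bad}")
    if np.any(arr[:, 1] < 0):
        raise ValueError(f"{path}: negative intensity")
    return Spectrum(meta["sample_id"], role, meta["batch"], arr)


def write_spectra(spectra: Iterable[Spectrum], outdir: str | Path) -> Path:
    """Write one peak-list TSV per spectrum plus a manifest TSV; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample_id}.tsv"
        write_peaklist(s, outdir / fname)
        rows.append({"sample_id": s.sample_id, "file": fname, "role": s.role.value})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_peaklists(manifest_path: str | Path) -> list[Spectrum]:
    """Load all spectra referenced by a manifest TSV (columns sample_id, file, role)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    for col in ("sample_id", "file", "role"):
        if col not in table.columns:
            raise ValueError(f"manifest missing column {col!r}")
    base = manifest_path.parent
    spectra = []
    for _, row in table.iterrows():
        fp = base / str(row["file"])
        if not fp.exists():
            raise FileNotFoundError(f"manifest references missing file {fp}")
        s = read_peaklist(fp)
        declared = Role(str(row["role"]))
        if s.role != declared:
            raise ValueError(
                f"{fp}: role {s.role.value!r} in file disagrees with manifest {declared.value!r}"
            )
        spectra.append(s)
    return spectra


def _decode_mzml_array(node, ns: str) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    import base64
    import zlib

    accessions = {c.get("accession") for c in node.findall(f"{ns}cvParam")}
    data = base64.b64decode((node.findtext(f"{ns}binary") or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(data, dtype=dtype).astype(float)


def read_mzml(path: str | Path, sample_id: str | None = None, role: str = "sample",
              batch: str = "b1") -> Spectrum:
    """Read all scans of an mzML file as one composite centroided spectrum.

    Direct-infusion acquisitions have no chromatographic dimension, so scans
    are merged by summing intensity at identical m/z. Decoding handles the
    standard mzML binary encodings (base64, optional zlib, 32/64-bit float).
    """
    from lxml import etree

    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = "{%s}" % root.nsmap.get(None) if root.nsmap.get(None) else ""
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    for spec_node in root.iter(f"{ns}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for arr_node in spec_node.iter(f"{ns}binaryDataArray"):
            acc = {c.get("accession") for c in arr_node.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:  # m/z array
                arrays["mz"] = _decode_mzml_array(arr_node, ns)
            elif "MS:1000515" in acc:  # intensity array
                arrays["intensity"] = _decode_mzml_array(arr_node, ns)
        if "mz" in arrays and "intensity" in arrays:
            mzs.append(arrays["mz"])
            intens.append(arrays["intensity"])
    if not mzs:
        raise ValueError(f"{path}: no spectra found")
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    uniq, inv = np.unique(mz, return_inverse=True)
    merged = np.zeros_like(uniq)
    np.add.at(merged, inv, inten)
    return Spectrum(sample_id or path.stem, Role(role), batch, np.column_stack([uniq, merged]))


def write_library(library: Sequence[LipidTarget], path: str | Path) -> Path:
    pd.DataFrame(
        {
            "name": [t.name for t in library],
            "lipid_class": [t.lipid_class for t in library],
            "expected_mz": [t.expected_mz for t in library],
        }
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_library(path: str | Path) -> list[LipidTarget]:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        LipidTarget(str(r["name"]), str(r["lipid_class"]), float(r["expected_mz"]))
        for _, r in table.iterrows()
    ]


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> Path:
    clinical.to_csv(path, sep="\t", index=True)
    return Path(path)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id", float_precision="round_trip")


def write_matrix(m: FeatureMatrix, prefix: str | Path) -> tuple[Path, Path | None]:
    """Write intensities (and deviations, if present) as TSV; returns the paths."""
    prefix = Path(prefix)
    ipath = prefix.with_suffix(".intensities.tsv")
    out = m.intensities.copy()
    out.insert(0, "_role", m.row_roles)
    out.to_csv(ipath, sep="\t", index=True, index_label="sample_id")
    dpath = None
    if m.deviations is not None:
        dpath = prefix.with_suffix(".deviations.tsv")
        m.deviations.to_csv(dpath, sep="\t", index=True, index_label="sample_id")
    meta = prefix.with_suffix(".meta.json")
    with open(meta, "w") as fh:
        json.dump({"cohort_id": m.cohort_id, "transform_log": m.transform_log}, fh, indent=1)
    return ipath, dpath


def read_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    table = pd.read_csv(prefix.with_suffix(".intensities.tsv"), sep="\t",
                        index_col="sample_id", float_precision="round_trip")
    roles = table.pop("_role")
    dpath = prefix.with_suffix(".deviations.tsv")
    deviations = (
        pd.read_csv(dpath, sep="\t", index_col="sample_id", float_precision="round_trip")
        if dpath.exists()
        else None
    )
    meta_path = prefix.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FeatureMatrix(
        intensities=table,
        deviations=deviations,
        transform_log=list(meta.get("transform_log", [])),
        cohort_id=meta.get("cohort_id", "cohort"),
        row_roles=roles,
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
    return path
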