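"""File I/O: FCS event files, delimited text, and JSON model documents.

The FCS support is a small, self-contained reader/writer for list-mode
FCS 2.0/3.0/3.1 files restricted to what one-dimensional profiling needs:
extracting a single named channel of float or integer events. Spillover
compensation, gating and the full keyword zoo are out of scope. The
writer emits minimal single-data-segment FCS 3.0 (float32, little-endian)
and exists to produce fixtures and round-trip tests.

Model documents serialize a fitted mixture (and optionally its merge
path) to JSON at full float precision; the scale entry stores the
variance sigma2, not sigma.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .merging import MergePath
from .mixture import FitResult, STNMixture, bic
from .stn import STNParams

__all__ = ["read_fcs", "write_fcs", "read_events_text", "write_events_text",
           "model_to_document", "document_to_model", "save_model",
           "load_model"]

MODEL_FORMAT_VERSION = "stnprofiler-model-1"


# ---------------------------------------------------------------------------
# FCS

class FCSError(ValueError):
    pass


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].decode("ascii", "replace").strip().upper():
            parts[i + 1].decode("ascii", "replace").strip()
            for i in range(0, len(parts), 2)}


def _read_fcs_dataset(buf: bytes):
    version = buf[:6].decode("ascii", "replace")
    if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
        raise FCSError(f"unsupported FCS version {version!r}")

    def offset(a: int, b: int) -> int:
        s = buf[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_start, text_end = offset(10, 18), offset(18, 26)
    data_start, data_end = offset(26, 34), offset(34, 42)
    text = _parse_text_segment(buf[text_start:text_end + 1])
    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if data_end <= data_start:
        raise FCSError("cannot locate the DATA segment")
    return text, buf[data_start:data_end + 1]


def read_fcs(path, channel: str) -> np.ndarray:
    """Events of one named FCS channel, in acquisition order, untransformed.

    The channel is matched against the $PnN (short) and $PnS (stain) names,
    case-insensitively. Unknown channels raise an error listing what the
    file does contain.
    """
    buf = Path(path).read_bytes()
    try:
        text, data = _read_fcs_dataset(buf)
    except (ValueError, IndexError, UnicodeDecodeError) as exc:
        raise FCSError(f"{path}: not a parseable FCS file: {exc}") from exc

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSError(f"{path}: only list-mode ($MODE=L) data supported")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    stains = [text.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    target = channel.strip().lower()
    idx = None
    for i, (nm, st) in enumerate(zip(names, stains)):
        if target in (nm.strip().lower(), st.strip().lower()):
            idx = i
            break
    if idx is None:
        raise FCSError(f"{path}: no channel named {channel!r}; available: "
                       f"{', '.join(names)}")

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if dtype_code == "F":
        arr = np.frombuffer(data[:4 * n_par * n_tot],
                            dtype=f"{order}f4").reshape(n_tot, n_par)
    elif dtype_code == "D":
        arr = np.frombuffer(data[:8 * n_par * n_tot],
                            dtype=f"{order}f8").reshape(n_tot, n_par)
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FCSError(f"{path}: unsupported integer layout $PnB={bits}")
        width = bits[0] // 8
        arr = np.frombuffer(data[:width * n_par * n_tot],
                            dtype=f"{order}u{width}").reshape(n_tot, n_par)
    else:
        raise FCSError(f"{path}: unsupported $DATATYPE={dtype_code}")
    if arr.shape[0] != n_tot:
        raise FCSError(f"{path}: DATA segment holds {arr.shape[0]} events "
                       f"but $TOT says {n_tot}")
    return np.ascontiguousarray(arr[:, idx], dtype=float)


def write_fcs(path, channels: dict[str, np.ndarray]) -> None:
    """Write a minimal single-dataset FCS 3.0 file (float32, little-endian)."""
    names = list(channels)
    cols = [np.asarray(channels[nm], dtype="<f4") for nm in names]
    n_tot = cols[0].size
    if any(c.size != n_tot for c in cols):
        raise ValueError("all channels must have the same number of events")
    data = np.column_stack(cols).astype("<f4").tobytes()

    delim = "/"
    kv = {"$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
          "$PAR": str(len(names)), "$TOT": str(n_tot),
          "$NEXTDATA": "0"}
    for i, nm in enumerate(names, start=1):
        kv[f"$P{i}N"] = nm
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(1.0, np.ceil(float(np.max(cols[i - 1]))
                                                 if n_tot else 1.0))))
    # two-pass layout: text length depends on the data offsets it encodes
    header_len = 58
    for _ in range(3):
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data) - 1
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
    header = (f"FCS3.0    {text_start:>8d}{text_end:>8d}"
              f"{data_start:>8d}{data_end:>8d}{0:>8d}{0:>8d}")
    assert len(header) == header_len
    Path(path).write_bytes(header.encode("ascii") + text.encode("ascii")
                           + data)


# ---------------------------------------------------------------------------
# delimited text

def read_events_text(path) -> np.ndarray:
    """One numeric value per line; blank lines and '#' comments skipped."""
    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            try:
                vals.append(float(s))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: not a number: {s!r}") from exc
    return np.array(vals, dtype=float)


def write_events_text(path, y: np.ndarray) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(y, dtype=float).ravel():
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# JSON model documents

def model_to_document(fit: FitResult,
                      merge: Optional[MergePath] = None) -> dict:
    """JSON-ready document for a fitted mixture (scales stored as sigma2)."""
    m = fit.model
    doc = {
        "format": MODEL_FORMAT_VERSION,
        "mixture": {
            "weights": [float(w) for w in m.weights],
            "components": [{"xi": c.xi, "sigma2": c.sigma2,
                            "lam": c.lam, "nu": c.nu}
                           for c in m.components],
        },
        "fit": {
            "n": fit.n,
            "loglik": fit.loglik,
            "bic": bic(fit),
            "converged": bool(fit.converged),
            "n_iter": fit.n_iter,
            "options": asdict(fit.options),
        },
    }
    if merge is not None:
        doc["merge"] = {
            "entropies": [float(e) for e in merge.entropies],
            "merged_pairs": [list(p) for p in merge.merged_pairs],
            "members_per_stage": [[list(ms) for ms in cp.members]
                                  for cp in merge.stages],
        }
    return doc


def document_to_model(doc: dict) -> tuple[STNMixture, dict]:
    """Rebuild the mixture and return it with the fit-metadata dict."""
    if doc.get("format") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unrecognized model document format "
                         f"{doc.get('format')!r}")
    mx = doc["mixture"]
    mixture = STNMixture(
        np.array(mx["weights"], dtype=float),
        tuple(STNParams(c["xi"], c["sigma2"], c["lam"], c["nu"])
              for c in mx["components"]))
    return mixture, doc.get("fit", {})


def save_model(path, fit: FitResult, merge: Optional[MergePath] = None) -> None:
    Path(path).write_text(json.dumps(model_to_document(fit, merge), indent=2))


def load_model(path) -> tuple[STNMixture, dict]:
    return document_to_model(json.loads(Path(path).read_text()))
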