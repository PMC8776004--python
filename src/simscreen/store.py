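"""FPS-style text fingerprint store and hit export.

The store is a plain-text format: ``#``-prefixed header lines carrying the
method tag and every parameter needed to fingerprint a query consistently,
then one record per line (payload TAB identifier).  Payload encoding depends
on the method:

=============  =================================================
fp2/ecfp4/
pharm2d        hex-encoded bit vector
e3fp           ``|``-separated hex bit vectors, one per conformer
mhfp6          comma-separated minima
erg            ``prop,prop,dist:value;...`` sparse entries
es5d           ``|``-separated conformers of 18 comma-separated reals
murcko/
generic        canonical scaffold SMILES key
=============  =================================================

Reading validates header/body consistency and reports corrupt lines with
their line number.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .errors import StoreFormatError, StoreMismatchError
from .fingerprints2d import BitFingerprint, ErGVector, MinHashSignature
from .fingerprints3d import ES5DVector
from .screening import METHODS_2D, METHODS_3D, SCAFFOLD_KINDS, ScreenHit

FORMAT_TAG = "simscreen/1"

_INT_PARAMS = {"length", "k", "seed", "radius", "max_distance", "n_conformers",
               "conformer_seed", "level"}
_FLOAT_PARAMS = {"fuzz", "charge_scale", "lipo_scale", "radius_multiplier"}


@dataclass
class FingerprintStore:
    method: str
    params: dict = field(default_factory=dict)
    entries: list[tuple[str, object]] = field(default_factory=list)
    created: str = ""

    def featurize_params(self) -> dict:
        """Keyword arguments for :func:`simscreen.screening.featurize` that
        reproduce this store's fingerprint settings for a query."""
        p = dict(self.params)
        if self.method == "mhfp6":
            return {k: p[k] for k in ("radius", "k", "seed") if k in p}
        if self.method in ("fp2", "ecfp4", "pharm2d"):
            return {k: p[k] for k in ("length",) if k in p}
        if self.method == "erg":
            return {k: p[k] for k in ("max_distance", "fuzz") if k in p}
        if self.method == "es5d":
            return {
                k: p[k]
                for k in ("charge_scale", "lipo_scale", "n_conformers",
                          "conformer_seed")
                if k in p
            }
        if self.method == "e3fp":
            return {
                k: p[k]
                for k in ("level", "radius_multiplier", "length",
                          "n_conformers", "conformer_seed")
                if k in p
            }
        return {}


def _encode_payload(method: str, payload) -> str:
    if method in ("fp2", "ecfp4", "pharm2d"):
        return payload.to_hex()
    if method == "e3fp":
        return "|".join(fp.to_hex() for fp in payload)
    if method == "mhfp6":
        return ",".join(str(m) for m in payload.minima)
    if method == "erg":
        return ";".join(
            f"{a},{b},{d}:{v!r}" for (a, b, d), v in sorted(payload.entries.items())
        )
    if method == "es5d":
        return "|".join(
            ",".join(repr(c) for c in vec.components) for vec in payload
        )
    if method in SCAFFOLD_KINDS:
        return payload if isinstance(payload, str) else payload.key
    raise ValueError(f"unknown method: {method}")


def _decode_payload(method: str, text: str, params: dict):
    if method in ("fp2", "ecfp4", "pharm2d"):
        return BitFingerprint.from_hex(text, params["length"])
    if method == "e3fp":
        return [
            BitFingerprint.from_hex(part, params["length"])
            for part in text.split("|")
        ]
    if method == "mhfp6":
        minima = tuple(int(v) for v in text.split(","))
        return MinHashSignature(params["k"], params["seed"], minima)
    if method == "erg":
        vec = ErGVector(max_distance=params["max_distance"])
        if text:
            for part in text.split(";"):
                key_part, val = part.split(":")
                a, b, d = key_part.split(",")
                vec.entries[(a, b, int(d))] = float(val)
        return vec
    if method == "es5d":
        return [
            ES5DVector(tuple(float(c) for c in part.split(",")))
            for part in text.split("|")
        ]
    if method in SCAFFOLD_KINDS:
        return text
    raise ValueError(f"unknown method: {method}")


def write_store(path, method: str, params: dict, entries: list[tuple[str, object]]):
    """Write a homogeneous fingerprint store to ``path``."""
    if method not in METHODS_2D + METHODS_3D + SCAFFOLD_KINDS:
        raise ValueError(f"unknown method: {method}")
    lines = [f"#{FORMAT_TAG}", f"#method={method}"]
    for key in sorted(params):
        lines.append(f"#param {key}={params[key]}")
    lines.append(f"#created={datetime.now(timezone.utc).isoformat()}")
    lines.append(f"#count={len(entries)}")
    for lib_id, payload in entries:
        if "\t" in lib_id or "\n" in lib_id:
            raise ValueError(f"identifier contains tab/newline: {lib_id!r}")
        lines.append(f"{_encode_payload(method, payload)}\t{lib_id}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_store(path) -> FingerprintStore:
    """Read and validate a fingerprint store.

    Raises
    ------
    StoreFormatError
        on malformed headers or corrupt body lines (with line number).
    """
    method = None
    params: dict = {}
    created = ""
    count = None
    entries: list[tuple[str, object]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if entries:
                    raise StoreFormatError("header line after body", lineno)
                body = line[1:]
                if lineno == 1:
                    if body != FORMAT_TAG:
                        raise StoreFormatError(
                            f"unknown format tag {body!r}", lineno
                        )
                elif body.startswith("method="):
                    method = body.split("=", 1)[1]
                elif body.startswith("param "):
                    kv = body[len("param "):]
                    key, val = kv.split("=", 1)
                    if key in _INT_PARAMS:
                        params[key] = int(val)
                    elif key in _FLOAT_PARAMS:
                        params[key] = float(val)
                    else:
                        params[key] = val
                elif body.startswith("created="):
                    created = body.split("=", 1)[1]
                elif body.startswith("count="):
                    count = int(body.split("=", 1)[1])
                else:
                    raise StoreFormatError(f"unknown header line {line!r}", lineno)
                continue
            if method is None:
                raise StoreFormatError("body before method header", lineno)
            parts = line.split("\t")
            if len(parts) != 2:
                raise StoreFormatError("expected payload<TAB>id", lineno)
            payload_text, lib_id = parts
            try:
                payload = _decode_payload(method, payload_text, params)
            except (ValueError, KeyError) as exc:
                raise StoreFormatError(f"corrupt payload ({exc})", lineno) from exc
            entries.append((lib_id, payload))
    if method is None:
        raise StoreFormatError("missing method header")
    if count is not None and count != len(entries):
        raise StoreFormatError(
            f"header count={count} but {len(entries)} records"
        )
    return FingerprintStore(
        method=method, params=params, entries=entries, created=created
    )


def check_query_compatible(store: FingerprintStore, **query_params):
    """Reject mismatched query settings (e.g. differing bit length)."""
    for key, val in query_params.items():
        if key in store.params and store.params[key] != val:
            raise StoreMismatchError(
                f"store {key}={store.params[key]} but query requested {val}"
            )


def export_hits(hits: list[ScreenHit], path=None) -> str:
    """Render hits as CSV (columns: id, score, rank, method).

    Scores print with 3 decimals; scaffold-search hits have an empty score
    column.  Returns the CSV text; writes it to ``path`` when given.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["id", "score", "rank", "method"])
    for hit in hits:
        score = "" if hit.score is None else f"{hit.score:.3f}"
        writer.writerow([hit.library_id, score, hit.rank, hit.method])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
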