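"""mzML 1.1 reading and writing.

The centerpiece is :func:`stream_spectra`, a single-pass incremental
reader: the XML is fed to a pull parser in small chunks and each spectrum
is decoded and yielded as soon as its closing tag arrives, so the first
scan of a multi-gigabyte file is available after reading only its head.
The trailing byte-offset index of an ``indexedmzML`` wrapper is ignored —
the reader is sequential by design.

:func:`reference_parse` is the deliberate opposite: it loads the whole
document into a DOM and then extracts records.  It exists as a
correctness oracle for the streaming path, not for production use.

Binary arrays are base64-encoded little-endian IEEE floats, 32- or
64-bit, optionally zlib-compressed, per the PSI controlled vocabulary.
"""

from __future__ import annotations

import base64
import binascii
import hashlib
import io
import zlib
from pathlib import Path
from typing import BinaryIO, Iterable, Iterator

import numpy as np
from lxml import etree

from .model import MsPoint, MzmlDialect, PointSet, SpectrumRecord

__all__ = [
    "MzmlError",
    "MzmlParseError",
    "UnsupportedDialectError",
    "IntegrityError",
    "decode_binary",
    "encode_binary",
    "stream_spectra",
    "reference_parse",
    "spectra_to_points",
    "collect_points",
    "write_mzml",
    "subset_spectra",
    "detect_dialect",
]

# PSI-MS / UO controlled-vocabulary accessions used by this module.
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"
ACC_FLOAT64 = "MS:1000523"
ACC_FLOAT32 = "MS:1000521"
ACC_ZLIB = "MS:1000574"
ACC_NO_COMPRESSION = "MS:1000576"
ACC_SCAN_START_TIME = "MS:1000016"
ACC_MS_LEVEL = "MS:1000511"
ACC_UNIT_SECOND = "UO:0000010"
ACC_UNIT_MINUTE = "UO:0000031"

_PRECISION_BY_ACC = {ACC_FLOAT64: "float64", ACC_FLOAT32: "float32"}
_COMPRESSION_BY_ACC = {ACC_ZLIB: "zlib", ACC_NO_COMPRESSION: "none"}
_DTYPE = {"float64": np.dtype("<f8"), "float32": np.dtype("<f4")}

_CHUNK = 16 * 1024  # bytes fed to the pull parser per step


class MzmlError(Exception):
    """Base class for mzML I/O failures."""


class MzmlParseError(MzmlError):
    """Malformed XML or structurally invalid mzML."""


class UnsupportedDialectError(MzmlError):
    """A binary array declares a precision/compression this reader lacks."""


class IntegrityError(MzmlError):
    """Declared lengths disagree with the actual payload."""


# ---------------------------------------------------------------------------
# binary array codec


def decode_binary(encoded: str, precision: str = "float64",
                  compression: str = "none") -> np.ndarray:
    """Decode a base64 (optionally zlib-compressed) float array."""
    dtype = _DTYPE.get(precision)
    if dtype is None:
        raise UnsupportedDialectError(f"unsupported precision {precision!r}")
    if compression not in ("none", "zlib"):
        raise UnsupportedDialectError(f"unsupported compression {compression!r}")
    try:
        raw = base64.b64decode(encoded.encode("ascii"), validate=True)
    except (binascii.Error, UnicodeEncodeError) as exc:
        raise MzmlParseError(f"invalid base64 payload: {exc}") from exc
    if compression == "zlib":
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise MzmlParseError(f"zlib inflate failed: {exc}") from exc
    if len(raw) % dtype.itemsize:
        raise IntegrityError(
            f"payload of {len(raw)} bytes is not a multiple of "
            f"element size {dtype.itemsize}"
        )
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def encode_binary(values: Iterable[float], precision: str = "float64",
                  compression: str = "none") -> str:
    """Inverse of :func:`decode_binary`; returns base64 text."""
    dtype = _DTYPE.get(precision)
    if dtype is None:
        raise UnsupportedDialectError(f"unsupported precision {precision!r}")
    raw = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=dtype).tobytes()
    if compression == "zlib":
        raw = zlib.compress(raw)
    elif compression != "none":
        raise UnsupportedDialectError(f"unsupported compression {compression!r}")
    return base64.b64encode(raw).decode("ascii")


# ---------------------------------------------------------------------------
# shared element decoding


def _localname(tag) -> str:
    if isinstance(tag, str) and tag.startswith("{"):
        return tag.rsplit("}", 1)[1]
    return tag if isinstance(tag, str) else ""


def _iter_cvparams(elem) -> Iterator[dict]:
    for child in elem:
        if _localname(child.tag) == "cvParam":
            yield child.attrib


def _decode_array_elem(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values).

    kind is "mz", "intensity", or None for arrays this reader skips.
    """
    kind = None
    precision = None
    compression = None
    for attrs in _iter_cvparams(bda):
        acc = attrs.get("accession", "")
        if acc == ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == ACC_INTENSITY_ARRAY:
            kind = "intensity"
        elif acc in _PRECISION_BY_ACC:
            precision = _PRECISION_BY_ACC[acc]
        elif acc in _COMPRESSION_BY_ACC:
            compression = _COMPRESSION_BY_ACC[acc]
    if kind is None:
        return None, np.empty(0)
    if precision is None:
        raise UnsupportedDialectError(
            f"{kind} array declares no recognized precision CV term"
        )
    if compression is None:
        compression = "none"
    binary = None
    for child in bda:
        if _localname(child.tag) == "binary":
            binary = child.text or ""
    if binary is None:
        raise MzmlParseError(f"{kind} binaryDataArray has no <binary> element")
    binary = "".join(binary.split())
    declared = bda.get("encodedLength")
    if declared is not None and int(declared) != len(binary):
        raise IntegrityError(
            f"encodedLength={declared} but base64 payload has {len(binary)} chars"
        )
    return kind, decode_binary(binary, precision, compression)


def _scan_start_time_seconds(spectrum) -> float:
    for node in spectrum.iter():
        if _localname(node.tag) != "cvParam":
            continue
        if node.get("accession") == ACC_SCAN_START_TIME:
            value = float(node.get("value"))
            unit = node.get("unitAccession", ACC_UNIT_SECOND)
            if unit == ACC_UNIT_MINUTE:
                value *= 60.0
            elif unit != ACC_UNIT_SECOND:
                raise UnsupportedDialectError(
                    f"unknown scan start time unit {unit!r}"
                )
            return value
    return 0.0


def _record_from_spectrum(spectrum, ordinal: int) -> SpectrumRecord:
    ms_level = 1
    for attrs in _iter_cvparams(spectrum):
        if attrs.get("accession") == ACC_MS_LEVEL:
            ms_level = int(attrs["value"])
    rt = _scan_start_time_seconds(spectrum)
    mz = intensity = None
    for node in spectrum.iter():
        if _localname(node.tag) == "binaryDataArray":
            kind, values = _decode_array_elem(node)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
    if mz is None or intensity is None:
        raise MzmlParseError(
            f"spectrum index {ordinal} lacks m/z and/or intensity arrays"
        )
    declared = spectrum.get("defaultArrayLength")
    if declared is not None and int(declared) != mz.size:
        raise IntegrityError(
            f"defaultArrayLength={declared} but decoded {mz.size} m/z values"
        )
    if mz.size != intensity.size:
        raise IntegrityError(
            f"m/z array ({mz.size}) and intensity array ({intensity.size}) "
            "lengths differ"
        )
    return SpectrumRecord(
        index=ordinal,
        scan_start_time=rt,
        ms_level=ms_level,
        mz_values=mz,
        intensity_values=intensity,
    )


# ---------------------------------------------------------------------------
# streaming reader


def _open_source(source) -> tuple[BinaryIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rb"), True
    if isinstance(source, (bytes, bytearray)):
        return io.BytesIO(source), True
    return source, False  # caller-owned file-like


def stream_spectra(source, ms_level_filter: int | None = None
                   ) -> Iterator[SpectrumRecord]:
    """Lazily yield :class:`SpectrumRecord` from an mzML byte stream.

    The source (path, bytes, or binary file-like) is read exactly once,
    front to back, in small chunks; each spectrum is yielded as soon as
    it is complete.  Works identically for plain ``mzML`` and
    ``indexedmzML`` files — the trailing index is never consulted.
    Retention times are normalized to seconds.
    """
    fh, owned = _open_source(source)
    consumed = 0
    parser = etree.XMLPullParser(events=("end",), recover=False)
    ordinal = 0
    try:
        while True:
            chunk = fh.read(_CHUNK)
            if chunk:
                consumed += len(chunk)
            try:
                if chunk:
                    parser.feed(chunk)
                else:
                    parser.close()
            except etree.XMLSyntaxError as exc:
                raise MzmlParseError(
                    f"malformed XML near byte offset {consumed}: {exc}"
                ) from exc
            for _event, elem in parser.read_events():
                name = _localname(elem.tag)
                if name == "spectrum":
                    record = _record_from_spectrum(elem, ordinal)
                    ordinal += 1
                    # free the subtree and any exhausted older siblings
                    elem.clear()
                    parent = elem.getparent()
                    if parent is not None:
                        while len(parent) > 1:
                            del parent[0]
                    if ms_level_filter is None or record.ms_level == ms_level_filter:
                        yield record
                elif name in ("chromatogram", "indexList", "index"):
                    elem.clear()
            if not chunk:
                break
    finally:
        if owned:
            fh.close()


def reference_parse(source, ms_level_filter: int | None = None
                    ) -> list[SpectrumRecord]:
    """Whole-document (DOM) reader used as a correctness oracle.

    Loads the entire XML tree into memory first, then walks it to
    extract every spectrum.  Must agree record-for-record with
    :func:`stream_spectra`.
    """
    fh, owned = _open_source(source)
    try:
        try:
            tree = etree.parse(fh)
        except etree.XMLSyntaxError as exc:
            raise MzmlParseError(f"malformed XML: {exc}") from exc
    finally:
        if owned:
            fh.close()
    records = []
    ordinal = 0
    for spectrum in tree.iter():
        if _localname(spectrum.tag) != "spectrum":
            continue
        record = _record_from_spectrum(spectrum, ordinal)
        ordinal += 1
        if ms_level_filter is None or record.ms_level == ms_level_filter:
            records.append(record)
    return records


# ---------------------------------------------------------------------------
# flattening scans into the point cloud


def spectra_to_points(spectra: Iterable[SpectrumRecord]) -> Iterator[MsPoint]:
    """Flatten scans into points; ids run sequentially from 0 in file order."""
    next_id = 0
    for record in spectra:
        rt = record.scan_start_time
        for mz, inten in zip(record.mz_values, record.intensity_values):
            yield MsPoint(next_id, float(mz), rt, float(inten))
            next_id += 1


def collect_points(spectra: Iterable[SpectrumRecord]) -> PointSet:
    """Materialize :func:`spectra_to_points` into a columnar PointSet."""
    mz_parts, rt_parts, int_parts = [], [], []
    for record in spectra:
        n = record.mz_values.size
        if n == 0:
            continue
        mz_parts.append(record.mz_values)
        int_parts.append(record.intensity_values)
        rt_parts.append(np.full(n, record.scan_start_time))
    if not mz_parts:
        return PointSet()
    mz = np.concatenate(mz_parts)
    return PointSet(np.arange(mz.size, dtype=np.int64), mz,
                    np.concatenate(rt_parts), np.concatenate(int_parts))


# ---------------------------------------------------------------------------
# writer


_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '{open_wrapper}'
    '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
    '  <cvList count="2">\n'
    '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
    ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
    '    <cv id="UO" fullName="Unit Ontology"'
    ' URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>\n'
    '  </cvList>\n'
    '  <fileDescription>\n'
    '    <fileContent>\n'
    '      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
    '      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
    '    </fileContent>\n'
    '  </fileDescription>\n'
    '  <softwareList count="1">\n'
    '    <software id="mzlod" version="0.1.0"/>\n'
    '  </softwareList>\n'
    '  <instrumentConfigurationList count="1">\n'
    '    <instrumentConfiguration id="IC1"/>\n'
    '  </instrumentConfigurationList>\n'
    '  <dataProcessingList count="1">\n'
    '    <dataProcessing id="DP1">\n'
    '      <processingMethod order="1" softwareRef="mzlod"/>\n'
    '    </dataProcessing>\n'
    '  </dataProcessingList>\n'
    '  <run id="run1" defaultInstrumentConfigurationRef="IC1">\n'
    '    <spectrumList count="{count}" defaultDataProcessingRef="DP1">\n'
)

_FOOTER = "    </spectrumList>\n  </run>\n</mzML>\n"

_PRECISION_PARAM = {
    "float64": '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
    "float32": '<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>',
}
_COMPRESSION_PARAM = {
    "none": '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
    "zlib": '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>',
}
_UNIT_ATTRS = {
    "second": 'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
    "minute": 'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"',
}


def _fmt(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips
    return repr(float(x))


def _spectrum_xml(record: SpectrumRecord, dialect: MzmlDialect) -> str:
    rt = record.scan_start_time
    if dialect.rt_unit_in_file == "minute":
        rt = rt / 60.0
    arrays = []
    for values, acc, name, unit in (
        (record.mz_values, ACC_MZ_ARRAY, "m/z array",
         ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'),
        (record.intensity_values, ACC_INTENSITY_ARRAY, "intensity array",
         ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'),
    ):
        b64 = encode_binary(values, dialect.precision, dialect.compression)
        arrays.append(
            f'          <binaryDataArray encodedLength="{len(b64)}">\n'
            f"            {_PRECISION_PARAM[dialect.precision]}\n"
            f"            {_COMPRESSION_PARAM[dialect.compression]}\n"
            f'            <cvParam cvRef="MS" accession="{acc}" name="{name}"'
            f' value=""{unit}/>\n'
            f"            <binary>{b64}</binary>\n"
            f"          </binaryDataArray>\n"
        )
    return (
        f'      <spectrum index="{record.index}" id="scan={record.index + 1}"'
        f' defaultArrayLength="{record.mz_values.size}">\n'
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level"'
        f' value="{record.ms_level}"/>\n'
        f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        f'        <scanList count="1">\n'
        f'          <scan>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"'
        f' value="{_fmt(rt)}" {_UNIT_ATTRS[dialect.rt_unit_in_file]}/>\n'
        f"          </scan>\n"
        f"        </scanList>\n"
        f'        <binaryDataArrayList count="2">\n'
        + "".join(arrays)
        + "        </binaryDataArrayList>\n"
        "      </spectrum>\n"
    )


def write_mzml(spectra: Iterable[SpectrumRecord], destination,
               dialect: MzmlDialect | None = None) -> None:
    """Write spectra as schema-conformant mzML 1.1.

    With ``dialect.indexed_wrapper`` the output is wrapped in
    ``indexedmzML`` with correct byte offsets for every spectrum.
    Output bytes are a pure function of the inputs.
    """
    dialect = dialect or MzmlDialect()
    records = list(spectra)
    for i, record in enumerate(records):
        if record.index != i:
            # renumber defensively: indexes must be the 0-based file order
            record = SpectrumRecord(i, record.scan_start_time, record.ms_level,
                                    record.mz_values, record.intensity_values)
            records[i] = record

    body_parts = [_spectrum_xml(r, dialect) for r in records]
    if not dialect.indexed_wrapper:
        text = (_HEADER.format(open_wrapper="", count=len(records))
                + "".join(body_parts) + _FOOTER)
        data = text.encode("utf-8")
    else:
        wrapper_open = '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml">\n'
        head = _HEADER.format(open_wrapper=wrapper_open, count=len(records))
        data = (head + "".join(body_parts) + _FOOTER).encode("utf-8")
        offsets = []
        cursor = len(head.encode("utf-8"))
        for part in body_parts:
            encoded = part.encode("utf-8")
            rel = encoded.index(b"<spectrum ")
            offsets.append(cursor + rel)
            cursor += len(encoded)
        index_lines = [
            '<indexList count="1">\n',
            '  <index name="spectrum">\n',
        ]
        for i, off in enumerate(offsets):
            index_lines.append(f'    <offset idRef="scan={i + 1}">{off}</offset>\n')
        index_lines.append("  </index>\n</indexList>\n")
        index_list_offset = len(data)
        tail = "".join(index_lines)
        tail += f"<indexListOffset>{index_list_offset}</indexListOffset>\n"
        sha1 = hashlib.sha1(data + tail.encode("utf-8") + b"<fileChecksum>")
        tail += f"<fileChecksum>{sha1.hexdigest()}</fileChecksum>\n</indexedmzML>\n"
        data = data + tail.encode("utf-8")

    if isinstance(destination, (str, Path)):
        with open(destination, "wb") as fh:
            fh.write(data)
    else:
        destination.write(data)


# ---------------------------------------------------------------------------
# dialect detection and subsetting


def detect_dialect(source) -> MzmlDialect:
    """Infer precision/compression/wrapper/RT-unit from a file's head."""
    fh, owned = _open_source(source)
    indexed = False
    precision = None
    compression = "none"
    rt_unit = "second"
    parser = etree.XMLPullParser(events=("start", "end"), recover=False)
    try:
        done = False
        while not done:
            chunk = fh.read(_CHUNK)
            try:
                if chunk:
                    parser.feed(chunk)
                else:
                    break
            except etree.XMLSyntaxError as exc:
                raise MzmlParseError(f"malformed XML: {exc}") from exc
            for event, elem in parser.read_events():
                name = _localname(elem.tag)
                if event == "start" and name == "indexedmzML":
                    indexed = True
                elif event == "end" and name == "cvParam":
                    acc = elem.get("accession", "")
                    if acc == ACC_SCAN_START_TIME:
                        if elem.get("unitAccession") == ACC_UNIT_MINUTE:
                            rt_unit = "minute"
                    elif acc in _PRECISION_BY_ACC and precision is None:
                        precision = _PRECISION_BY_ACC[acc]
                    elif acc == ACC_ZLIB:
                        compression = "zlib"
                elif event == "end" and name == "spectrum":
                    done = True  # the first spectrum fixes the dialect
                    break
    finally:
        if owned:
            fh.close()
    return MzmlDialect(
        precision=precision or "float64",
        compression=compression,
        indexed_wrapper=indexed,
        rt_unit_in_file=rt_unit,
    )


def subset_spectra(source, k: int, destination) -> None:
    """Write a new mzML file holding exactly the first ``k`` spectra.

    The output keeps the source's dialect.  ``k`` must satisfy
    ``1 <= k <= total spectrum count``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    dialect = detect_dialect(source)
    first_k: list[SpectrumRecord] = []
    total = 0
    for record in stream_spectra(source):
        total += 1
        if total <= k:
            first_k.append(record)
    if k > total:
        raise ValueError(f"k={k} exceeds the {total} spectra in the source")
    write_mzml(first_k, destination, dialect)
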