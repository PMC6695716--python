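"""Readers and writers for the device's text and XML formats.

Three on-disk dialects:

* raw inductive streams — whitespace-separated non-negative integers
  (16-bit converter counts), optionally with ``#`` comment lines;
* mobile-ECG RestingECG XML records, whose ``WaveFormData`` payload is a
  sequence of hex tokens: ``FF`` opens a new frame, and each 4-hex-digit
  token is one big-endian 16-bit sample.  Each lead carries a CRC-32 of
  its decoded sample bytes;
* recording filenames of the form ``YYYY_MM_DD-HH_MM_SS.xml``.

Parsing is strict about element names (including the device's
``DateofBirth``/``NumberofLeads`` spellings).  CRC verification is a
separate step: a parsed record always retains the stored CRC, and
`verify_lead_crc` reports mismatches without failing the parse, since
field records are routinely truncated at transfer boundaries.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from lxml import etree

from .signals import Signal

__all__ = [
    "RestingEcgRecord",
    "LeadData",
    "read_inductive_text",
    "write_inductive_text",
    "parse_resting_ecg_xml",
    "write_resting_ecg_xml",
    "parse_waveform_hex",
    "format_waveform_hex",
    "crc32",
    "lead_sample_bytes",
    "verify_lead_crc",
    "make_filename",
    "parse_filename",
    "example_record_path",
    "read_ecg_csv",
    "write_ecg_csv",
]


# --------------------------------------------------------------------------
# raw inductive text streams

def read_inductive_text(source, fs: float = 20.0) -> Signal:
    """Read a whitespace-separated stream of 16-bit counts.

    ``source`` is a path or an open text file.  Lines starting with ``#``
    are generator provenance headers and are skipped.  A malformed token
    raises with its line number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    values: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        for token in stripped.split():
            try:
                value = int(token)
            except ValueError:
                raise ValueError(f"line {lineno}: invalid sample token {token!r}") from None
            if value < 0:
                raise ValueError(f"line {lineno}: negative count {value}")
            values.append(value)
    if not values:
        raise ValueError("empty inductive stream")
    return Signal(np.asarray(values, dtype=float), fs, "counts")


def write_inductive_text(s: Signal, path, header: dict | None = None) -> None:
    """Write a counts signal, one sample per line, with ``#`` header lines."""
    lines = []
    if header:
        for key, value in header.items():
            lines.append(f"# {key} = {value}")
    lines.extend(str(int(round(v))) for v in s.samples)
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# ECG CSV (time_s, mV)

def write_ecg_csv(s: Signal, path) -> None:
    data = np.column_stack([s.times, s.samples])
    np.savetxt(path, data, delimiter=",", header="time_s,mV", comments="", fmt="%.6f")


def read_ecg_csv(path) -> Signal:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("ECG CSV must have two columns (time_s, mV) and >= 2 rows")
    dt = np.diff(data[:, 0])
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("ECG CSV time column is not uniformly sampled")
    return Signal(data[:, 1], 1.0 / dt[0], "millivolt")


# --------------------------------------------------------------------------
# WaveFormData hex dialect

_HEX4 = re.compile(r"^[0-9A-Fa-f]{4}$")


def parse_waveform_hex(text: str, strict: bool = True) -> list[list[int]]:
    """Decode a WaveFormData payload into frames of 16-bit samples.

    ``FF`` starts a new frame; every 4-hex-digit token is one big-endian
    16-bit sample appended to the current frame.  A sample token before
    any ``FF`` is an error.  With ``strict=False`` a malformed *trailing*
    token is dropped with a warning (truncated field records); malformed
    tokens elsewhere always raise.
    """
    tokens = text.split()
    frames: list[list[int]] = []
    for pos, token in enumerate(tokens):
        if token.upper() == "FF":
            frames.append([])
            continue
        if not _HEX4.match(token):
            if not strict and pos == len(tokens) - 1:
                warnings.warn(
                    f"dropping malformed trailing WaveFormData token {token!r}",
                    stacklevel=2,
                )
                break
            raise ValueError(f"token {pos}: {token!r} is neither 'FF' nor 4 hex digits")
        if not frames:
            raise ValueError(f"token {pos}: sample {token!r} appears before any FF frame marker")
        frames[-1].append(int(token, 16))
    return frames


def format_waveform_hex(frames: list[list[int]]) -> str:
    """Inverse of :func:`parse_waveform_hex` (uppercase, space-separated)."""
    parts: list[str] = []
    for frame in frames:
        parts.append("FF")
        for sample in frame:
            if not (0 <= sample <= 0xFFFF):
                raise ValueError(f"sample {sample} outside the 16-bit range")
            parts.append(f"{sample:04X}")
    return " ".join(parts)


def crc32(payload: bytes) -> int:
    """Standard CRC-32 (IEEE 802.3: reflected, init/final XOR 0xFFFFFFFF)."""
    return zlib.crc32(payload) & 0xFFFFFFFF


def lead_sample_bytes(frames: list[list[int]]) -> bytes:
    """Big-endian byte serialization of all samples, frame order preserved."""
    out = bytearray()
    for frame in frames:
        for sample in frame:
            out += int(sample).to_bytes(2, "big")
    return bytes(out)


# --------------------------------------------------------------------------
# RestingECG XML records

@dataclass(frozen=True)
class LeadData:
    amplitude_units_per_bit: float
    lead_id: int
    crc32: int
    frames: list[list[int]]

    def __post_init__(self) -> None:
        if not (0 <= self.crc32 < 2**32):
            raise ValueError("CRC32 must be an unsigned 32-bit value")
        for frame in self.frames:
            for sample in frame:
                if not (0 <= sample <= 0xFFFF):
                    raise ValueError("lead samples must be 16-bit")


@dataclass(frozen=True)
class RestingEcgRecord:
    patient_id: str
    date_of_birth: str
    gender: str
    waveform_type: str
    number_of_leads: int
    sample_type: str
    sample_base: int
    battery: str
    leads: list[LeadData]

    def __post_init__(self) -> None:
        if self.sample_base <= 0:
            raise ValueError("SampleBase must be positive")
        if self.number_of_leads != len(self.leads):
            raise ValueError(
                f"NumberofLeads = {self.number_of_leads} but {len(self.leads)} LeadData elements"
            )


def _required(parent, name: str):
    node = parent.find(name)
    if node is None or node.text is None:
        raise ValueError(f"missing required element <{name}>")
    return node.text.strip()


def parse_resting_ecg_xml(source, strict_waveform: bool = False) -> RestingEcgRecord:
    """Parse a RestingECG XML record (path, file object, or bytes/str).

    Element names follow the device dialect exactly (``DateofBirth``,
    ``NumberofLeads``, ...).  The stored CRC is kept as read; use
    :func:`verify_lead_crc` to check it against the decoded samples.
    """
    parser = etree.XMLParser(resolve_entities=False, load_dtd=False, no_network=True)
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        tree = etree.parse(str(source), parser)
        root = tree.getroot()
    else:
        data = source if isinstance(source, bytes) else str(source).encode("iso-8859-1")
        root = etree.fromstring(data, parser)
    if root.tag != "RestingECG":
        raise ValueError(f"expected root <RestingECG>, got <{root.tag}>")

    waveform = root.find("Waveform")
    if waveform is None:
        raise ValueError("missing required element <Waveform>")
    lead_nodes = waveform.findall("LeadData")
    if not lead_nodes:
        raise ValueError("missing required element <LeadData>")

    leads = []
    for node in lead_nodes:
        frames = parse_waveform_hex(_required(node, "WaveFormData"), strict=strict_waveform)
        leads.append(
            LeadData(
                amplitude_units_per_bit=float(_required(node, "LeadAmplitudeUnitsPerBit")),
                lead_id=int(_required(node, "LeadID")),
                crc32=int(_required(node, "LeadDataCRC32")),
                frames=frames,
            )
        )
    return RestingEcgRecord(
        patient_id=_required(root, "PatientID"),
        date_of_birth=_required(root, "DateofBirth"),
        gender=_required(root, "Gender"),
        waveform_type=_required(waveform, "WaveformType"),
        number_of_leads=int(_required(waveform, "NumberofLeads")),
        sample_type=_required(waveform, "SampleType"),
        sample_base=int(_required(waveform, "SampleBase")),
        battery=_required(waveform, "Battery"),
        leads=leads,
    )


def write_resting_ecg_xml(record: RestingEcgRecord, path) -> None:
    """Serialize a record back to the device XML dialect."""
    root = etree.Element("RestingECG")
    etree.SubElement(root, "PatientID").text = record.patient_id
    etree.SubElement(root, "DateofBirth").text = record.date_of_birth
    etree.SubElement(root, "Gender").text = record.gender
    waveform = etree.SubElement(root, "Waveform")
    etree.SubElement(waveform, "WaveformType").text = record.waveform_type
    etree.SubElement(waveform, "NumberofLeads").text = str(record.number_of_leads)
    etree.SubElement(waveform, "SampleType").text = record.sample_type
    etree.SubElement(waveform, "SampleBase").text = str(record.sample_base)
    etree.SubElement(waveform, "Battery").text = record.battery
    for lead in record.leads:
        node = etree.SubElement(waveform, "LeadData")
        etree.SubElement(node, "LeadAmplitudeUnitsPerBit").text = repr(lead.amplitude_units_per_bit)
        etree.SubElement(node, "LeadID").text = str(lead.lead_id)
        etree.SubElement(node, "LeadDataCRC32").text = str(lead.crc32)
        etree.SubElement(node, "WaveFormData").text = format_waveform_hex(lead.frames)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="ISO-8859-1", pretty_print=True)


def verify_lead_crc(record: RestingEcgRecord) -> list[bool]:
    """Per-lead check of the stored CRC against the decoded sample bytes."""
    return [crc32(lead_sample_bytes(lead.frames)) == lead.crc32 for lead in record.leads]


def example_record_path() -> Path:
    """Path to the packaged sample RestingECG record."""
    return Path(str(resources.files("inducardio").joinpath("data/example_resting_ecg.xml")))


# --------------------------------------------------------------------------
# filename convention

_FILENAME_RE = re.compile(r"^(\d{4})_(\d{2})_(\d{2})-(\d{2})_(\d{2})_(\d{2})\.xml$")


def make_filename(timestamp: _dt.datetime) -> str:
    """Recording filename: ``YYYY_MM_DD-HH_MM_SS.xml`` (zero-padded)."""
    return timestamp.strftime("%Y_%m_%d-%H_%M_%S") + ".xml"


def parse_filename(name: str) -> _dt.datetime:
    """Inverse of :func:`make_filename`."""
    m = _FILENAME_RE.match(name)
    if not m:
        raise ValueError(f"{name!r} does not match YYYY_MM_DD-HH_MM_SS.xml")
    return _dt.datetime(*(int(g) for g in m.groups()))
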