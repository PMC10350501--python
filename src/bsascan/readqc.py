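"""Seven-step raw-read cleaning and per-cycle diagnostics.

The cleaning procedure, applied to every read in order:

1. remove the 3' sequencing adapter (exact prefix match, minimum 5 bp overlap);
2. trim the 5' end while the base is below Q20 or is an N;
3. trim the 3' end while the base is below Q3 or is an N;
4. scan 4-base windows 5'->3' and truncate at the first window whose mean
   quality is below Q20 (then re-apply the 3' rule to any newly exposed tail,
   so cleaning is idempotent);
5. drop the read if its N fraction is >= 10%;
6. drop the read if more than 40% of its bases are below Q15;
7. drop the read if fewer than 30 bp remain.

Quality strings are Phred+33.  Surviving reads are always contiguous
substrings of the input read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._util import open_text_write

PHRED_OFFSET = 33

STEP_ADAPTER = 1
STEP_TRIM5 = 2
STEP_TRIM3 = 3
STEP_WINDOW = 4
STEP_NRATE = 5
STEP_LOWQ = 6
STEP_LENGTH = 7
STEPS = (STEP_ADAPTER, STEP_TRIM5, STEP_TRIM3, STEP_WINDOW, STEP_NRATE, STEP_LOWQ, STEP_LENGTH)


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the seven cleaning steps (defaults are the standard ones)."""

    q5_min: int = 20            # step 2: 5' bases below this (or N) are cut
    q3_min: int = 3             # step 3: 3' bases below this (or N) are cut
    window: int = 4             # step 4: window width...
    window_mean_q: float = 20.0  # ...and its mean-quality floor
    max_n_frac: float = 0.10    # step 5: drop when N fraction >= this
    lowq_phred: int = 15        # step 6: a base below this is "low quality"...
    max_lowq_frac: float = 0.40  # ...drop when their fraction exceeds this
    min_len: int = 30           # step 7: drop shorter reads
    min_adapter_overlap: int = 5


@dataclass
class ReadRecord:
    id: str
    seq: str
    qual: np.ndarray  # integer Phred scores, same length as seq

    def __post_init__(self):
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id!r}: sequence length {len(self.seq)} != quality length {len(self.qual)}")

    @classmethod
    def from_strings(cls, rid: str, seq: str, qual_str: str) -> "ReadRecord":
        qual = np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(np.int16) - PHRED_OFFSET
        return cls(rid, seq, qual)

    def qual_string(self) -> str:
        return "".join(chr(int(q) + PHRED_OFFSET) for q in self.qual)


@dataclass
class CleanResult:
    read: ReadRecord | None            # None when dropped
    dropped_at: int | None             # step number that dropped the read
    trimmed: dict = field(default_factory=dict)  # step -> bases removed

    @property
    def kept(self) -> bool:
        return self.read is not None


def find_adapter_start(seq: str, adapter: str, min_overlap: int = 5) -> int | None:
    """Leftmost position where the adapter (or a >=min_overlap prefix of it at
    the read end) starts, or None."""
    n, alen = len(seq), len(adapter)
    for p in range(0, n - min_overlap + 1):
        k = min(alen, n - p)
        if seq[p:p + k] == adapter[:k]:
            return p
    return None


def clean_read(read: ReadRecord, adapter: str | None = None,
               params: QCParams = QCParams()) -> CleanResult:
    """Apply the seven cleaning steps to one read."""
    seq, qual = read.seq, read.qual
    if len(seq) != len(qual):
        raise ValueError(f"read {read.id!r}: malformed record")
    trimmed: dict[int, int] = {}

    if adapter:
        p = find_adapter_start(seq, adapter, params.min_adapter_overlap)
        if p is not None:
            trimmed[STEP_ADAPTER] = len(seq) - p
            seq, qual = seq[:p], qual[:p]

    i = 0
    while i < len(seq) and (qual[i] < params.q5_min or seq[i] == "N"):
        i += 1
    if i:
        trimmed[STEP_TRIM5] = i
        seq, qual = seq[i:], qual[i:]

    j = len(seq)
    while j > 0 and (qual[j - 1] < params.q3_min or seq[j - 1] == "N"):
        j -= 1
    if j < len(seq):
        trimmed[STEP_TRIM3] = len(seq) - j
        seq, qual = seq[:j], qual[:j]

    w = params.window
    if len(seq) >= w:
        # compare window sums (exact for integer quals) against mean*width
        sums = np.convolve(qual, np.ones(w), mode="valid")
        bad = np.nonzero(sums < params.window_mean_q * w)[0]
        if len(bad):
            cut = int(bad[0])
            trimmed[STEP_WINDOW] = len(seq) - cut
            seq, qual = seq[:cut], qual[:cut]
            # re-trim the newly exposed 3' tail so cleaning is idempotent
            j = len(seq)
            while j > 0 and (qual[j - 1] < params.q3_min or seq[j - 1] == "N"):
                j -= 1
            if j < len(seq):
                trimmed[STEP_WINDOW] += len(seq) - j
                seq, qual = seq[:j], qual[:j]

    if len(seq) and seq.count("N") / len(seq) >= params.max_n_frac:
        return CleanResult(None, STEP_NRATE, trimmed)
    if len(seq) and (qual < params.lowq_phred).sum() / len(seq) > params.max_lowq_frac:
        return CleanResult(None, STEP_LOWQ, trimmed)
    if len(seq) < params.min_len:
        return CleanResult(None, STEP_LENGTH, trimmed)
    return CleanResult(ReadRecord(read.id, seq, qual), None, trimmed)


@dataclass
class QCReport:
    """Stream-level accounting plus per-cycle diagnostics of the *input* reads."""

    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0
    dropped: dict = field(default_factory=lambda: {s: 0 for s in STEPS})
    trimmed_bases: dict = field(default_factory=lambda: {s: 0 for s in STEPS})
    _comp: np.ndarray = field(default_factory=lambda: np.zeros((0, 5), dtype=np.int64))
    _err_sum: np.ndarray = field(default_factory=lambda: np.zeros(0))
    _cycle_n: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    _BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}

    def _grow(self, length: int) -> None:
        if length > len(self._cycle_n):
            pad = length - len(self._cycle_n)
            self._comp = np.vstack([self._comp, np.zeros((pad, 5), dtype=np.int64)])
            self._err_sum = np.append(self._err_sum, np.zeros(pad))
            self._cycle_n = np.append(self._cycle_n, np.zeros(pad, dtype=np.int64))

    def add_input_read(self, read: ReadRecord) -> None:
        L = len(read.seq)
        self.reads_in += 1
        self.bases_in += L
        self._grow(L)
        for i, b in enumerate(read.seq):
            self._comp[i, self._BASE_INDEX.get(b, 4)] += 1
        self._err_sum[:L] += 10.0 ** (-read.qual / 10.0)
        self._cycle_n[:L] += 1

    def add_result(self, result: CleanResult) -> None:
        for step, n in result.trimmed.items():
            self.trimmed_bases[step] += n
        if result.kept:
            self.reads_out += 1
            self.bases_out += len(result.read.seq)
        else:
            self.dropped[result.dropped_at] += 1

    def cycle_table(self) -> pd.DataFrame:
        """Per-cycle base-composition fractions and mean error rate (10^(-Q/10))."""
        n = np.maximum(self._cycle_n, 1)
        frac = self._comp / n[:, None]
        df = pd.DataFrame(frac, columns=list("ACGTN"))
        df.insert(0, "cycle", np.arange(1, len(df) + 1))
        df["mean_error_rate"] = self._err_sum / n
        df["n_reads"] = self._cycle_n
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# reads_in\t{self.reads_in}\n# reads_out\t{self.reads_out}\n")
            fh.write(f"# bases_in\t{self.bases_in}\n# bases_out\t{self.bases_out}\n")
            for s in STEPS:
                fh.write(f"# dropped_step{s}\t{self.dropped[s]}\n")
            for s in STEPS:
                fh.write(f"# trimmed_bases_step{s}\t{self.trimmed_bases[s]}\n")
            self.cycle_table().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def parse_fastq(path) -> Iterator[ReadRecord]:
    """Stream a (possibly gzipped) FASTQ, validating record structure."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"truncated FASTQ record at index {idx}")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record at index {idx}")
            yield ReadRecord.from_strings(header[1:].split()[0], seq.upper(), qual)
            idx += 1


def qc_stream(fastq_in, fastq_out=None, adapter: str | None = None,
              params: QCParams = QCParams()) -> QCReport:
    """Clean every read of a FASTQ stream, optionally writing survivors out."""
    report = QCReport()
    out_fh = open_text_write(fastq_out) if fastq_out is not None else None
    try:
        for read in parse_fastq(fastq_in):
            report.add_input_read(read)
            result = clean_read(read, adapter=adapter, params=params)
            report.add_result(result)
            if result.kept and out_fh is not None:
                r = result.read
                out_fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual_string()}\n")
    finally:
        if out_fh is not None:
            out_fh.close()
    return report
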