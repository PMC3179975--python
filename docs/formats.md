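# On-disk formats

`nmrproc` reads and writes two simplified vendor-style dialects, a
metabolite shift-library text format, and a CSV data-matrix export.  All
formats are plain text or documented raw binary; writers live in
`nmrproc.synthetic`, readers in `nmrproc.io`.

## Bruker-style dialect

A dataset is a directory containing:

- `fid` (1D) or `ser` (2D): the time-domain data as interleaved
  real/imaginary 32-bit signed integers (`re0 im0 re1 im1 ...`).  Byte
  order is little-endian when `BYTORDA= 0`, big-endian when `BYTORDA= 1`.
  For 1D data, `GRPDLY` zero-valued complex points precede the signal
  (digital-filter delay); the reader removes them by a circular left shift
  followed by truncation.  For 2D data, rows (t1 increments) are
  concatenated; when two quadrature channels are present (`NCHAN= 2` in
  `acqu2s`) the channels alternate row by row (channel A, channel B,
  channel A, ...).
- `acqus` (direct dimension) and, for 2D, `acqu2s` (indirect dimension):
  one `##$KEY= value` pair per line (JCAMP-DX flavoured).  Keys:

  | key          | meaning                                            |
  |--------------|----------------------------------------------------|
  | `SW`         | spectral width, Hz                                 |
  | `SFO1`       | spectrometer frequency, MHz                        |
  | `O1`         | transmitter offset, Hz (`O1 / SFO1` gives ppm)     |
  | `TD`         | total stored values = 2 x complex points incl. delay |
  | `GRPDLY`     | digital-filter delay, complex points               |
  | `BYTORDA`    | 0 little-endian, 1 big-endian                      |
  | `SCALE`      | power-of-two factor the float data were multiplied by before integer rounding |
  | `TE`         | sample temperature, Kelvin (optional)              |
  | `QUADSCHEME` | 2D only: `states`, `echo-antiecho` or `none`       |
  | `F1UNIT`     | 2D only: `ppm` or `hz` axis for F1                 |
  | `NCHAN`      | `acqu2s` only: quadrature channels per increment   |

  `SW`, `SFO1`, `O1` and `TD` are mandatory; a missing key is a parse
  error naming the key.  `TD` must be even.

  The writer chooses `SCALE` as the power of two that fills the int32
  range, so reading divides by `SCALE` and recovers the data to ~2^-30
  relative precision — exactly, when the original values are integers.

## Varian-style dialect

A dataset directory contains:

- `fid`: a 16-byte big-endian header of four int32 values
  `(magic = 0x6e6d7266, n_complex, group_delay, reserved)` followed by
  interleaved real/imaginary big-endian float32 data (group-delay points
  included, as in the Bruker dialect).
- `procpar`: one `key value` pair per line.  Mandatory keys: `sw` (Hz),
  `sfrq` (MHz), `tof` (offset, Hz), `np` (total stored values).  Optional:
  `grpdly`, `temp` (Celsius).

## Shift library

Human-editable text; `#` starts a comment, blank lines are ignored:

```
[glutamate]
CA  3.7430  55.5800
CB  2.0400  27.8400
```

One `[metabolite]` block per compound, one atom per line:
`ATOM_LABEL  1H_ppm  13C_ppm`.  Atom labels must be unique within a
metabolite.  A small synthetic fixture library ships as
`nmrproc/data/library.txt`.

## Matrix export

`io.export_matrix` writes CSV with columns `id,class,<ppm>,<ppm>,...`:
one row per included spectrum, one column per included axis point, the
header carrying ppm values printed with 4 decimals.  `io.read_matrix`
reads it back.
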