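# data/

Drop-in location for external input tables.

`s1_spharm_coefficients.xlsx` (or `.csv`) — the original cohort's
supplementary table of all 144 SPHARM coefficients per bone (18 left,
18 right).  Expected layout: either one sheet per side named `left` /
`right` with one row per bone and one numeric column per coefficient, or a
single sheet/CSV with a `side` column.  The legacy binary `.xls` container
is not parsed; convert to `.xlsx` or CSV first.  The file is not
redistributable with this package, so the one test and any analysis that
need it fail with a clear message until it is supplied.
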