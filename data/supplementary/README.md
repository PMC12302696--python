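# Supplementary cross-check data (not redistributed)

The cohort cross-check tests and acceptance targets t4-t7 reproduce published
per-participant statistics from the study's open-access supplementary data
archive. Those CSV tables are not redistributed in this repository.

To enable the cross-checks, download the supplementary archive from the
publisher (the S4 data tables, CSV format) and place:

    ResponseRatesBySubject.csv

into this directory. The loader (`souvenir.crosscheck`) matches the pre/post
rate columns case-insensitively by name and accepts values on either a 0-1 or
0-100 scale.

Without this file, `tests/test_acceptance.py::TestSupplementaryCrossCheck`
fails (by design — the check cannot be faked) and `scripts/acceptance.py`
omits targets t4-t7.
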