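# Reference coordinate fixtures

This directory holds the trimmed Cα-only PDB files for the two deposited
receptor structures used by the worked-example collective-variable checks
(`5ung_ca.pdb`, `6jod_ca.pdb`). They are not redistributed here; populate
them once with

    python scripts/fetch_reference_structures.py

which downloads the entries from the Protein Data Bank and keeps only the
Cα ATOM records (a few tens of kilobytes each). Without these files the two
corresponding acceptance tests fail with instructions.
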