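# data/

Drop external input structures here.  The benchmark acceptance tests
and `scripts/acceptance.py` look for `1CKU.pdb` in this directory
(obtain it with `redoxpot fetch 1CKU -o data/1CKU.pdb`; the build
environment had no network route to the PDB archive, so the file is
not bundled).
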