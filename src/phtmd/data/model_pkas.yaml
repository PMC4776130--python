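# Reference pKa values of the Ace-X-Nme model-compound side chains, matching
# the constant-pH force-field parametrization the sampler is validated
# against.  Edit or pass an override mapping to fixtures.model_compound to
# titrate against a different reference set.
asp: {pka_ref: 4.0, kind: acid}
glu: {pka_ref: 4.4, kind: acid}
his: {pka_ref: 6.5, kind: base}
cys: {pka_ref: 8.5, kind: acid}
tyr: {pka_ref: 9.6, kind: acid}
lys: {pka_ref: 10.4, kind: base}
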