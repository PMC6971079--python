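# Inferred ancestral insect mitochondrial gene order (pancrustacean ground
# pattern), linearized from the cox1 anchor on the majority strand.
# "-" prefix = minority strand.
ancestral_insect	cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cob trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY
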