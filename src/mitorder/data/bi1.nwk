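(outgroup,((G_uzeli,H_aculeatus),(F_vespiformis,(H_indicus,(R_cruentatus,((D_minowai,A_obscurus),((N_samayunkur,(S_dorsalis_EA,S_dorsalis_SA)),((F_intonsa,F_occidentalis),(T_imaginis,T_palmi)))))))));
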