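#Pdb;Mutation(s)_cleaned;Affinity_mut_parsed;Affinity_wt_parsed;Temperature
1ABC_A_B;LA38G;1e-6;1e-8;298
1ABC_A_B;EA40K;1e-9;1e-8;298
1ABC_A_B;LA38G,AA39G;1e-7;1e-8;298
2XYZ_A_B;TB12A;1e-7;1e-9;298
2XYZ_A_B;TB12A;2e-7;1e-9;298
2XYZ_A_B;SB14A;1e-5;1e-9;298
2XYZ_A_B;SB14A;2e-9;1e-9;298
3DEF_X_Y;GX5A;5e-8;1e-8;310
3DEF_X_Y;KX7R;1e-9;1e-8;298
3DEF_X_Y;YX9F;1e-8;1e-8;
4GHI_A_B;RA21E;1e-4;1e-6;298
4GHI_A_B;DA22aN;3e-6;1e-6;298
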