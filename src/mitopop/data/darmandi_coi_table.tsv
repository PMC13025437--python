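locality	haplogroup	n	haplotypes
Jzg	MSM	5	H01(2), H03(2), H06
Pw	MSM	5	H01, H02(2), H04(2)
Wc	MSM	7	H02(2), H05(2), H07, H08, H09
Wd	QLM	8	H02(3), H06(2), H07(3), H14
Kc	QLM	8	H03, H08, H11, H12(3), H17(2)
Ld	QLM	12	H05, H10(3), H13(2), H15(4), H17, H18, H19
Ly	QLM	5	H03(2), H10, H11(2)
Lb	QLM	5	H10, H15, H17, H19(2)
Fp	QLM	17	H13(3), H16, H17(4), H19(2), H20(3), H21(2), H22(2)
Ns	QLM	5	H19(2), H23, H24(2)
Hb	QLM	3	H17(2), H22
Xy	QLM	6	H18(2), H20, H21, H22, H24
Tb	QLM	5	H17, H18(2), H20(2)
Mc	QLM	4	H10(3), H20
Ca	QLM	8	H17, H19(3), H22, H23(3)
Lt	QLM	3	H19, H25(2)
Hz	QLM	4	H22, H24, H25(2)
Za	QLM	11	H20, H21(3), H22(2), H23(2), H25(3)
Sy	QLM	6	H21(2), H23(2), H25, H26
Sn	QLM	3	H19, H24, H25
Yx	QLM	5	H17, H19(2), H23, H25
Ls	QLM	12	H19(3), H20(4), H22(3), H23(2)
Lc	QLM	13	H17(3), H19(5), H20, H23(2), H25(2)
Nx	QLM	3	H23, H25, H26
Lsc	QLM	3	H23, H25(2)
Ct	MCM	5	H05(3), H28, H29
Wcc	MCM	5	H08(2), H27, H28, H32
Nz	MCM	8	H26(2), H28(3), H29, H30, H31
Nj	MCM	11	H29(3), H30, H33(3), H34(2), H35, H36
Zy	TPM	5	H17(2), H23, H39(2)
Wy	TPM	8	H30(3), H33, H34(2), H38(2)
Ck	TPM	6	H30, H32, H33(2), H36, H40
Pl	TPM	13	H37(3), H38, H39(4), H40, H41(3), H43
Wx	TPM	3	H39, H40, H41
Zx	TPM	7	H40(4), H41(2), H44
Fc	TPM	4	H42, H43(3)
Bk	TPM	3	H46, H47(2)
Slj	TPM	11	H38, H40(2), H41, H42(3), H45, H46, H47(2)
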