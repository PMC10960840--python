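# SYNTHETIC demonstration library: plausible mucin-type O-glycan
# alditol structures with computed m/z and modelled CCS values.
# Not measured data.
composition,structure,z,mz,ccs_tims,ccs_twims,source,accession
HexNAc1,GalNAc-ol,1,222.0983,111.7,111.5,PGM_synthetic,demo
Hex1HexNAc1,Gal(b1-3)GalNAc-ol,1,384.1511,160.8,161.3,PGM_synthetic,demo
HexNAc2,GlcNAc(b1-3)GalNAc-ol,1,425.1777,172.0,171.6,PGM_synthetic,demo
Hex1HexNAc1dHex1,Fuc(a1-2)Gal(b1-3)GalNAc-ol,1,530.2090,199.3,199.9,PGM_synthetic,demo
Hex1HexNAc2,Gal(b1-3)GlcNAc(b1-3)GalNAc-ol,1,587.2305,213.3,212.7,PGM_synthetic,demo
Hex1HexNAc2,Gal(b1-3)[GlcNAc(b1-6)]GalNAc-ol,1,587.2305,215.8,216.5,PGM_synthetic,demo
Hex1HexNAc2,Gal(b1-4)GlcNAc(b1-3)GalNAc-ol,1,587.2305,218.4,217.9,PGM_synthetic,demo
HexNAc3,GlcNAc(b1-3)[GlcNAc(b1-6)]GalNAc-ol,1,628.2571,223.1,223.7,PGM_synthetic,demo
Hex1HexNAc1NeuAc1,Gal(b1-3)[NeuAc(a2-6)]GalNAc-ol,1,675.2466,234.0,233.5,PGM_synthetic,demo
Hex1HexNAc1NeuAc1,NeuAc(a2-3)Gal(b1-3)GalNAc-ol,1,675.2466,236.9,237.6,PGM_synthetic,demo
Hex1HexNAc2dHex1,Fuc(a1-3)[Gal(b1-4)]GlcNAc(b1-3)GalNAc-ol,1,733.2884,247.3,246.6,PGM_synthetic,demo
Hex1HexNAc2dHex1,Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)GalNAc-ol,1,733.2884,250.2,251.0,PGM_synthetic,demo
Hex1HexNAc2dHex1,Fuc(a1-2)Gal(b1-3)[GlcNAc(b1-6)]GalNAc-ol,1,733.2884,253.2,252.6,PGM_synthetic,demo
Hex1HexNAc2dHex1,Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)GalNAc-ol,1,733.2884,256.2,257.0,PGM_synthetic,demo
Hex1HexNAc2dHex1,Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-3)GalNAc-ol,1,733.2884,259.2,258.5,PGM_synthetic,demo
Hex2HexNAc2,Gal(b1-3)[Gal(b1-3)GlcNAc(b1-6)]GalNAc-ol,1,749.2833,250.8,251.6,PGM_synthetic,demo
Hex2HexNAc2,Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,749.2833,253.9,253.2,PGM_synthetic,demo
Hex1HexNAc3,Gal(b1-4)GlcNAc(b1-3)[GlcNAc(b1-6)]GalNAc-ol,1,790.3099,259.9,260.7,PGM_synthetic,demo
Hex1HexNAc2NeuAc1,NeuAc(a2-3)Gal(b1-3)[GlcNAc(b1-6)]GalNAc-ol,1,878.3259,278.8,278.1,PGM_synthetic,demo
Hex1HexNAc2NeuAc1,NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-3)GalNAc-ol,1,878.3259,282.2,283.0,PGM_synthetic,demo
Hex2HexNAc2dHex1,Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)Gal(b1-3)GalNAc-ol,1,895.3412,282.4,281.7,PGM_synthetic,demo
Hex2HexNAc2dHex1,Fuc(a1-2)Gal(b1-3)[Gal(b1-3)GlcNAc(b1-6)]GalNAc-ol,1,895.3412,285.8,286.7,PGM_synthetic,demo
Hex2HexNAc2dHex1,Fuc(a1-2)Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,895.3412,289.2,288.5,PGM_synthetic,demo
Hex2HexNAc2dHex1,Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-3)GalNAc-ol,1,895.3412,292.6,293.5,PGM_synthetic,demo
Hex2HexNAc2dHex1,Gal(b1-3)[Fuc(a1-2)Gal(b1-3)GlcNAc(b1-6)]GalNAc-ol,1,895.3412,296.0,295.3,PGM_synthetic,demo
Hex2HexNAc2dHex1,Gal(b1-3)[Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,895.3412,299.4,300.3,PGM_synthetic,demo
Hex2HexNAc2dHex1,Gal(b1-3)[Fuc(a1-3)[Gal(b1-4)]GlcNAc(b1-6)]GalNAc-ol,1,895.3412,302.8,302.1,PGM_synthetic,demo
Hex2HexNAc3,Gal(b1-4)GlcNAc(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,952.3627,294.3,295.1,PGM_synthetic,demo
Hex1HexNAc1NeuAc2,NeuAc(a2-3)Gal(b1-3)[NeuAc(a2-6)]GalNAc-ol,1,966.3420,297.1,296.4,PGM_synthetic,demo
Hex2HexNAc2NeuAc1,Gal(b1-3)[NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1040.3787,312.1,313.0,PGM_synthetic,demo
Hex2HexNAc2NeuAc1,Gal(b1-3)[NeuAc(a2-6)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1040.3787,315.9,315.1,PGM_synthetic,demo
Hex2HexNAc2NeuAc1,NeuAc(a2-3)Gal(b1-3)GlcNAc(b1-3)Gal(b1-3)GalNAc-ol,1,1040.3787,319.6,320.6,PGM_synthetic,demo
Hex2HexNAc2NeuAc1,NeuAc(a2-3)Gal(b1-3)[Gal(b1-3)GlcNAc(b1-6)]GalNAc-ol,1,1040.3787,323.4,322.6,PGM_synthetic,demo
Hex2HexNAc2NeuAc1,NeuAc(a2-3)Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1040.3787,327.1,328.1,PGM_synthetic,demo
Hex2HexNAc2dHex2,Fuc(a1-2)Gal(b1-3)[Fuc(a1-2)Gal(b1-3)GlcNAc(b1-6)]GalNAc-ol,1,1041.3991,312.3,311.5,PGM_synthetic,demo
Hex2HexNAc2dHex2,Fuc(a1-2)Gal(b1-3)[Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1041.3991,316.1,317.0,PGM_synthetic,demo
Hex2HexNAc2dHex2,Fuc(a1-2)Gal(b1-3)[Fuc(a1-3)[Gal(b1-4)]GlcNAc(b1-6)]GalNAc-ol,1,1041.3991,319.8,319.0,PGM_synthetic,demo
Hex2HexNAc3dHex1,Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1098.4206,323.6,324.6,PGM_synthetic,demo
Hex3HexNAc3,Gal(b1-3)[Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1114.4155,326.7,325.9,PGM_synthetic,demo
Hex2HexNAc2dHex1NeuAc1,Fuc(a1-2)Gal(b1-3)[NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1186.4367,340.6,341.7,PGM_synthetic,demo
Hex2HexNAc2dHex1NeuAc1,Fuc(a1-2)Gal(b1-3)[NeuAc(a2-6)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1186.4367,344.7,343.9,PGM_synthetic,demo
Hex2HexNAc2dHex1NeuAc1,NeuAc(a2-3)Gal(b1-3)[Fuc(a1-2)Gal(b1-3)GlcNAc(b1-6)]GalNAc-ol,1,1186.4367,348.9,349.9,PGM_synthetic,demo
Hex2HexNAc2dHex1NeuAc1,NeuAc(a2-3)Gal(b1-3)[Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1186.4367,353.0,352.1,PGM_synthetic,demo
Hex2HexNAc2dHex1NeuAc1,NeuAc(a2-3)Gal(b1-3)[Fuc(a1-3)[Gal(b1-4)]GlcNAc(b1-6)]GalNAc-ol,1,1186.4367,357.1,358.1,PGM_synthetic,demo
Hex3HexNAc3dHex1,Fuc(a1-2)Gal(b1-3)[Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1260.4734,354.7,353.8,PGM_synthetic,demo
Hex3HexNAc3dHex1,Gal(b1-3)[Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1260.4734,358.9,360.0,PGM_synthetic,demo
Hex2HexNAc2NeuAc2,NeuAc(a2-3)Gal(b1-3)[NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1331.4742,367.8,366.9,PGM_synthetic,demo
Hex2HexNAc2NeuAc2,NeuAc(a2-3)Gal(b1-3)[NeuAc(a2-6)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1331.4742,372.3,373.4,PGM_synthetic,demo
Hex3HexNAc3NeuAc1,NeuAc(a2-3)Gal(b1-3)[Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-6)]GalNAc-ol,1,1405.5109,381.3,380.4,PGM_synthetic,demo
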