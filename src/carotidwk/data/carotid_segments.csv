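label,name,diameter_mm,length_mm,count,group,printed_resistance,printed_compliance,alt_length_mm,anomaly
B1,ICA (proximal segment),5.6,33.1,1,proximal,4.80e6,1.48e-12,,
B2,M1 (sphenoidal segment),2.66,19.6,1,ica-distal,5.60e7,1.07e-13,,
B3,Lateral lenticulostriate artery (LLS),0.47,21.9,9,ica-distal,6.40e10,6.60e-16,,
B4,M2 (insular segment),2.4,13.5,1,ica-distal,5.81e7,5.42e-14,,
B5,Anterior temporal artery (ATA),1.75,10,1,ica-distal,1.52e8,1.56e-14,,
B6,M3 (opercular segment),1.7,13.3,1,ica-distal,2.27e8,1.90e-14,,
B7,M4 (cortical segment),1,13.1,1,ica-distal,1.87e9,3.80e-15,,
B8,Angular artery,1.5,13,1,ica-distal,3.66e8,1.27e-14,,
B9,Temporopolar artery,0.85,13,1,ica-distal,3.55e9,2.32e-15,,
B10,Lateral orbitofrontal artery (LOFA),0.8,11.1,16,ica-distal,3.87e9,1.65e-15,,
B11,Anterior cerebral artery (origin),2.61,17.6,1,ica-distal,2.36e7,5.11e-14,7.68,reference resistance reproducible only with the alternate length 7.68 mm
B12,Recurrent artery of Heubner (A2),0.7,24,1,ica-distal,1.43e10,2.83e-15,,0.7 mm quoted elsewhere as a radius; kept as diameter per the source table
B13,Anterior cerebral artery (cortical segment),1.31,10,1,ica-distal,4.77e8,8.51e-15,,resistance reproduces only to about 1.5 percent; implied wall stiffness is an outlier
B14,A1 (horizontal or pre-communicating segment),2.5,20,1,ica-distal,7.30e7,1.17e-13,,
B15,A2 (infracallosal segment),3,42.1,1,ica-distal,7.42e7,3.91e-13,,
B16,A3 (precallosal segment),2,30,1,ica-distal,2.68e8,6.13e-14,,
B17,A4 (supracallosal segment),1.5,30,1,ica-distal,8.45e8,3.79e-14,,
B18,A5 (postcallosal segment),1,30,1,ica-distal,4.28e9,1.12e-14,,
B19,Anterior communicating artery,1.6,3,1,ica-distal,6.53e7,4.60e-15,,
B20,Medial lenticulostriate artery,0.4,20,9,ica-distal,1.11e11,3.27e-16,,not used by the published reduction chains
B21,Callosomarginal artery,1.85,10,1,ica-distal,1.22e8,2.18e-14,,not used by the published reduction chains
B22,Medial orbitofrontal artery (MOFA),1,7.9,15,ica-distal,1.13e9,2.72e-15,,
B23,Frontopolar artery,1.02,10.7,1,ica-distal,1.41e9,3.90e-15,,
B24,Subcallosal-hypothalamic perforating branches,0.4,5,7.6,ica-distal,2.79e10,1.10e-16,,
B25,Median callosal artery,0.75,5,1,ica-distal,2.25e9,7.25e-16,,
B26,Central retinal artery,0.16,7.5,1,ophthalmic,1.63e12,1.03e-18,,
B27,Posterior ciliary artery,0.1,5,1,ophthalmic,7.13e12,1.68e-19,,
B28,Ophthalmic artery,,,1,ophthalmic,1.33e12,1.20e-18,,composed element: parallel combination of B26 and B27; no geometry of its own
B29,Superior thyroid artery,2,30,1,eca-distal,2.68e8,8.09e-14,,
B30,Ascending pharyngeal artery,1,70,1,eca-distal,9.99e9,2.36e-14,,
B31,Lingual artery,2.5,67.5,1,eca-distal,2.47e8,3.55e-13,,
B32,Facial artery,3.2,28,1,eca-distal,3.81e7,3.09e-13,,
B33,Occipital artery,1.9,79.3,1,eca-distal,8.68e8,1.83e-13,,
B34,Posterior auricular artery,0.95,64,1,eca-distal,1.12e10,1.85e-14,,
B35,Maxillary artery,4.08,80,1,eca-distal,4.12e7,1.83e-12,,
B36,Superficial temporal artery,2.2,70,1,eca-distal,4.26e8,2.51e-13,,
B37,Proximal ECA main branch segment,4,20,1,proximal,1.11e7,4.31e-13,,
B38,Distal ECA main branch segment,3,20,1,eca-distal,3.52e7,1.82e-13,,
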