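(f1:14.984962190511,(((((t2:16.524930118290001,f3:9.473404235676):9.6020193905170004,f4:13.833132870861):4.8444259922209998,f5:11.789157737706001):2.5788572941019998,(t6:26.400844972270999,((t7:2.7374106773100002,((t8:0.64036566629900005,t9:0.64036566629900005):1.2445915799489999,t10:1.8849572462469999):0.85245343106299998):23.127769723463,t11:25.865180400772999):0.53566457149699997):7.1493878228590004):2.8729720531690002,((t12:23.197787508838001,(f13:5.3016773469410001,(t14:11.342868496111,f15:4.0191874642889998):11.728530065723):0.126388947004):9.6199098552660001,(((t16:8.1493966113670009,(t17:0.27559101028600003,t18:0.27559101028600003):7.8738056010799999):6.4902720397799998,t19:14.639668651147):2.0021886607930002,((t20:4.0705953457010002,t21:4.0705953457010002):9.2697470387519996,(t22:11.183558272265,((f23:2.1597397421540001,(t24:1.0692157422349999,(t25:0.48967538454800003,t26:0.48967538454800003):0.57954035768699996):3.5055951209949998):0.85323614482099996,t27:5.4280470080510002):5.7555112642150004):2.1567841121879998):3.3015149274870002):16.175840052163998):3.6055074841939998):17.43565431571);
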