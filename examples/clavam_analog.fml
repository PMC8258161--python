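<fluxml name="clavam_analog">
  <reactionnetwork>
    <metabolitepools>
      <pool id="GLX" atoms="3" type="input"/>
      <pool id="AGX" atoms="5" type="input"/>
      <pool id="G3" atoms="3" type="intra"/>
      <pool id="PY" atoms="3" type="intra"/>
      <pool id="AC" atoms="2" type="intra"/>
      <pool id="OA" atoms="4" type="intra"/>
      <pool id="CI" atoms="6" type="intra"/>
      <pool id="KG" atoms="5" type="intra"/>
      <pool id="SU" atoms="4" type="intra"/>
      <pool id="P5" atoms="5" type="intra"/>
      <pool id="AA" atoms="5" type="intra"/>
      <pool id="OR" atoms="4" type="intra"/>
      <pool id="CV" atoms="8" type="intra"/>
      <pool id="CO2" atoms="1" type="intra"/>
      <pool id="CVX" atoms="8" type="output"/>
      <pool id="BMP" atoms="3" type="output"/>
      <pool id="BMO" atoms="4" type="output"/>
      <pool id="BM5" atoms="5" type="output"/>
      <pool id="CO2X" atoms="1" type="output"/>
    </metabolitepools>
    <reaction id="upt_g">
      <reduct id="GLX" cx="abc"/>
      <rproduct id="G3" cx="abc"/>
    </reaction>
    <reaction id="upt_a">
      <reduct id="AGX" cx="abcde"/>
      <rproduct id="AA" cx="abcde"/>
    </reaction>
    <reaction id="emp" bidirectional="true">
      <reduct id="G3" cx="abc"/>
      <rproduct id="PY" cx="abc"/>
    </reaction>
    <reaction id="ppp">
      <reduct id="G3" cx="abc"/>
      <reduct id="G3" cx="def"/>
      <rproduct id="P5" cx="abcde"/>
      <rproduct id="CO2" cx="f"/>
    </reaction>
    <reaction id="pdh">
      <reduct id="PY" cx="abc"/>
      <rproduct id="AC" cx="bc"/>
      <rproduct id="CO2" cx="a"/>
    </reaction>
    <reaction id="tca1">
      <reduct id="AC" cx="ab"/>
      <reduct id="OA" cx="cdef"/>
      <rproduct id="CI" cx="abcdef"/>
    </reaction>
    <reaction id="tca2">
      <reduct id="CI" cx="abcdef"/>
      <rproduct id="KG" cx="abcde"/>
      <rproduct id="CO2" cx="f"/>
    </reaction>
    <reaction id="tca3">
      <reduct id="KG" cx="abcde"/>
      <rproduct id="SU" cx="bcde"/>
      <rproduct id="CO2" cx="a"/>
    </reaction>
    <reaction id="tca4" bidirectional="true">
      <reduct id="SU" cx="abcd"/>
      <rproduct id="OA" cx="abcd"/>
    </reaction>
    <reaction id="ana">
      <reduct id="PY" cx="abc"/>
      <reduct id="CO2" cx="d"/>
      <rproduct id="OA" cx="abcd"/>
    </reaction>
    <reaction id="ure1">
      <reduct id="AA" cx="abcde"/>
      <rproduct id="OR" cx="abcd"/>
      <rproduct id="CO2" cx="e"/>
    </reaction>
    <reaction id="ure2">
      <reduct id="OR" cx="abcd"/>
      <rproduct id="OA" cx="abcd"/>
    </reaction>
    <reaction id="clv">
      <reduct id="G3" cx="abc"/>
      <reduct id="AA" cx="defgh"/>
      <rproduct id="CV" cx="abcdefgh"/>
    </reaction>
    <reaction id="cv_out">
      <reduct id="CV" cx="abcdefgh"/>
      <rproduct id="CVX" cx="abcdefgh"/>
    </reaction>
    <reaction id="bm_py">
      <reduct id="PY" cx="abc"/>
      <rproduct id="BMP" cx="abc"/>
    </reaction>
    <reaction id="bm_oa">
      <reduct id="OA" cx="abcd"/>
      <rproduct id="BMO" cx="abcd"/>
    </reaction>
    <reaction id="bm_p5">
      <reduct id="P5" cx="abcde"/>
      <rproduct id="BM5" cx="abcde"/>
    </reaction>
    <reaction id="co2_out">
      <reduct id="CO2" cx="a"/>
      <rproduct id="CO2X" cx="a"/>
    </reaction>
  </reactionnetwork>
  <constraints>
    <net>
      <bounds lo="-100.0" hi="100.0"/>
      <textual>upt_a &lt;= 3.0; upt_a &gt;= 0.5; ppp &gt;= 0.5; pdh &gt;= 1.0; clv &gt;= 0.1; ure1 &gt;= 0.1</textual>
    </net>
    <xch>
      <bounds lo="0.0" hi="200.0"/>
    </xch>
  </constraints>
  <measurement>
    <mgroup id="ms_PY" spec="PY[1,2,3]#M0,1,2,3"/>
    <mgroup id="ms_OA" spec="OA[1,2,3,4]#M0,1,2,3,4"/>
    <mgroup id="ms_OA12" spec="OA[1,2]#M0,1,2"/>
    <mgroup id="ms_KG" spec="KG[1,2,3,4,5]#M0,1,2,3,4,5"/>
    <mgroup id="ms_SU" spec="SU[1,2,3,4]#M0,1,2,3,4"/>
    <mgroup id="ms_AA" spec="AA[1,2,3,4,5]#M0,1,2,3,4,5"/>
    <mgroup id="ms_AA25" spec="AA[2,3,4,5]#M0,1,2,3,4"/>
    <mgroup id="ms_P5" spec="P5[1,2,3,4,5]#M0,1,2,3,4,5"/>
    <mgroup id="ms_CV" spec="CV[1,2,3,4,5,6,7,8]#M0,1,2,3,4,5,6,7,8"/>
    <mgroup id="ms_CV13" spec="CV[1,2,3]#M0,1,2,3"/>
    <errormodel slope="0.0412" intercept="0.006655"/>
    <rate flux="upt_a" value="2.0" stddev="0.1"/>
    <rate flux="cv_out" value="1.0" stddev="0.05"/>
    <rate flux="co2_out" value="150.0" stddev="30.0"/>
  </measurement>
  <normalization flux="upt_g" value="100.0" fixed="true"/>
</fluxml>
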